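"""Conditional reversal enrichment of gene sets, shared across datasets.

For a gene set and a dataset, a 2x2 table is formed over the genes whose
developmental direction matches the conditioning direction: rows are the
reversal pattern versus the direction-matched monotone pattern (up-down
vs up-up when conditioning on developmental up-regulation; down-up vs
down-down when conditioning on down), columns are set membership. The
odds ratio OR = (a*d)/(b*c) measures conditional reversal enrichment;
a set is "shared" when OR > 1 in every dataset. Sharing is tested by
recomputing the shared-set count under the structured age permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import AgeSeriesDataset, DEFAULT_TURNING_AGE_YEARS
from .reversal import PermutationResult, TrendSignEngine

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "reversal_odds_ratio",
    "enrichment_table",
    "shared_enriched_sets",
    "enrichment_permutation_test",
    "deduplicate_gene_sets",
]

#: (reversal pattern, direction-matched monotone pattern) per conditioning
#: developmental direction.
CONDITIONAL_PAIRS = {"up": ("up-down", "up-up"), "down": ("down-up", "down-down")}


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared gene universe."""

    sets: dict[str, list]
    namespace: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def filter_min_size(self, min_size: int) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: m for n, m in self.sets.items() if len(m) >= min_size},
            namespace=self.namespace,
        )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Mapping, path,
              description: str = "na") -> None:
    items = collection.items() if hasattr(collection, "items") else collection
    with open(path, "w") as fh:
        for name, members in items:
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------


def reversal_odds_ratio(
    reversal_column: pd.Series, gene_set, dev_direction: str
) -> dict:
    """Conditional reversal odds ratio for one set in one dataset.

    The 2x2 counts are ``a`` (reversal pattern, in set), ``b``
    (monotone pattern, in set), ``c`` (reversal, out of set) and ``d``
    (monotone, out of set); OR = (a*d)/(b*c) on raw counts. A single
    zero in ``b`` or ``c`` gives an infinite OR (the sharing criterion
    is only OR > 1); an OR with no information in a margin (a = c = 0,
    or a = b = 0 with c = d = 0, etc.) is returned as NaN with
    ``defined=False`` and cannot count as shared.
    """
    if dev_direction not in CONDITIONAL_PAIRS:
        raise ValueError("dev_direction must be 'up' or 'down'")
    rev, mono = CONDITIONAL_PAIRS[dev_direction]
    in_set = reversal_column.index.isin(pd.Index(gene_set))
    is_rev = (reversal_column == rev).to_numpy()
    is_mono = (reversal_column == mono).to_numpy()
    a = int((is_rev & in_set).sum())
    b = int((is_mono & in_set).sum())
    c = int((is_rev & ~in_set).sum())
    d = int((is_mono & ~in_set).sum())
    defined = (a + b) > 0 and (c + d) > 0 and (a + c) > 0 and (b + d) > 0
    if not defined:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
        defined = a * d > 0
    else:
        odds = (a * d) / (b * c)
    return {"a": a, "b": b, "c": c, "d": d, "OR": odds, "defined": defined}


def enrichment_table(
    reversal_table: pd.DataFrame,
    collection: GeneSetCollection | Mapping,
    dev_direction: str,
    min_set_size: int = 10,
) -> pd.DataFrame:
    """Long-format 2x2 counts and ORs for every (set, dataset) pair.

    Sets smaller than ``min_set_size`` members are skipped.
    """
    items = collection.items() if hasattr(collection, "items") else collection.items()
    rows = []
    for name, members in items:
        if len(members) < min_set_size:
            continue
        for ds in reversal_table.columns:
            cell = reversal_odds_ratio(reversal_table[ds], members, dev_direction)
            rows.append({"set": name, "dataset": ds, **cell})
    return pd.DataFrame(rows)


def shared_enriched_sets(table: pd.DataFrame) -> list[str]:
    """Set names with a defined OR > 1 in every dataset."""
    if table.empty:
        return []
    ok = table.assign(hit=(table["OR"] > 1) & table["defined"])
    shared = ok.groupby("set")["hit"].all()
    return sorted(shared.index[shared])


def count_shared_enriched(
    reversal_table: pd.DataFrame,
    collection,
    dev_direction: str,
    min_set_size: int = 10,
) -> int:
    table = enrichment_table(reversal_table, collection, dev_direction, min_set_size)
    return len(shared_enriched_sets(table))


def _membership_matrix(collection, gene_index: pd.Index, min_set_size: int):
    """Boolean set x gene membership over the gene universe."""
    items = collection.items() if hasattr(collection, "items") else dict(collection).items()
    names, rows = [], []
    for name, members in items:
        if len(members) < min_set_size:
            continue
        names.append(name)
        rows.append(gene_index.isin(pd.Index(members)))
    if not names:
        raise ValueError("no gene set passes the minimum size filter")
    return names, np.array(rows)


def _count_shared_from_signs(
    dev_signs: pd.DataFrame, aging_signs: pd.DataFrame,
    membership: np.ndarray, dev_direction: str,
) -> int:
    """Shared enriched-set count computed directly from sign frames.

    Equivalent to scoring every (set, dataset) 2x2 table with
    :func:`reversal_odds_ratio` and applying the OR > 1 unanimity
    filter, but vectorized as membership-matrix products.
    """
    sd = 1 if dev_direction == "up" else -1
    sa = -sd
    membership = membership.astype(np.int64)
    shared = np.ones(membership.shape[0], dtype=bool)
    for name in dev_signs.columns:
        dcol = dev_signs[name].to_numpy()
        acol = aging_signs[name].to_numpy()
        is_rev = ((dcol == sd) & (acol == sa)).astype(np.int64)
        is_mono = ((dcol == sd) & (acol == sd)).astype(np.int64)
        a = membership @ is_rev
        b = membership @ is_mono
        c = is_rev.sum() - a
        d = is_mono.sum() - b
        margins = ((a + b) > 0) & ((c + d) > 0) & ((a + c) > 0) & ((b + d) > 0)
        shared &= (a * d > b * c) & margins
        if not shared.any():
            break
    return int(shared.sum())


def enrichment_permutation_test(
    datasets: Sequence[AgeSeriesDataset],
    collection: GeneSetCollection | Mapping,
    dev_direction: str,
    n_permutations: int = 1000,
    seed: int | None = None,
    turning_age_years: float = DEFAULT_TURNING_AGE_YEARS,
    min_set_size: int = 10,
    engine: TrendSignEngine | None = None,
) -> PermutationResult:
    """Structured permutation test of the shared enriched-set count.

    Each replicate permutes individual ages within source and period,
    reclassifies every gene in every dataset, rescores every set and
    recounts sets with OR > 1 everywhere.
    """
    if n_permutations < 1:
        raise ValueError("need >= 1 permutation")
    if engine is None:
        engine = TrendSignEngine(datasets, turning_age_years)
    _, membership = _membership_matrix(collection, engine.gene_union, min_set_size)
    observed = _count_shared_from_signs(*engine.signs(), membership, dev_direction)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = _count_shared_from_signs(
            *engine.permuted_signs(rng), membership, dev_direction
        )
    return PermutationResult(float(observed), null, n_permutations, seed)


def deduplicate_gene_sets(collection: GeneSetCollection | Mapping):
    """Collapse sets with identical membership to one representative.

    The lexicographically smallest name survives. Returns the reduced
    collection and a mapping of removed name -> retained name.
    """
    items = dict(collection.items() if hasattr(collection, "items") else collection)
    by_membership: dict[frozenset, list[str]] = {}
    for name in sorted(items):
        by_membership.setdefault(frozenset(items[name]), []).append(name)
    kept, removed = {}, {}
    for names in by_membership.values():
        keep = names[0]
        kept[keep] = items[keep]
        for other in names[1:]:
            removed[other] = keep
    kept = {n: kept[n] for n in sorted(kept)}
    if isinstance(collection, GeneSetCollection):
        return GeneSetCollection(kept, namespace=collection.namespace), removed
    return kept, removed
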