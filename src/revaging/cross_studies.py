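"""Comparisons of aging reversal with differentiation and disease changes.

Two external axes are compared with the development/aging reversal
patterns:

* an in-vitro neuronal differentiation series with three ordinal stages
  (iPSC -> neurosphere -> neuron), where genes up-regulated along the
  stages are candidates for neuronal-identity establishment; and
* case/control cohorts (Alzheimer's-style), where genes consistently
  shifted in cases across all cohorts define disease-related sets.

The central statistic is the conditioned reversal proportion: among a
conditioning gene set, the count of the reversal pattern divided by the
count of the direction-matched monotone pattern (reported as
num/(num+den) for the ">50% reversal" criterion). Significance comes
from two permutation schemes: structured age permutations of the
age-series datasets, and label permutations of the external study with
a top-N surrogate for the conditioning set (ranking genes by the
permuted effect and keeping the observed set size N, so that null
proportions are computed from sets of the same size as the observation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .preprocess import AgeSeriesDataset, DEFAULT_TURNING_AGE_YEARS
from .reversal import PermutationResult, TrendSignEngine
from .trajectories import spearman_rho_matrix, trend_table

__all__ = [
    "StageSeries",
    "CaseControlSet",
    "ReversalProportion",
    "stage_trends",
    "differentiation_up_genes",
    "conditioned_reversal_proportion",
    "aging_age_permutation_test",
    "topn_stage_permutation_test",
    "topn_case_control_permutation_test",
    "case_control_signs",
    "ad_consistent_genes",
    "ad_consistency_permutation_test",
    "dev_ad_overlap_proportion",
]


@dataclass
class StageSeries:
    """Expression matrix with an ordinal differentiation stage per sample."""

    expr: pd.DataFrame
    stages: pd.Series  # 1=iPSC, 2=neurosphere, 3=neuron

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.stages.index):
            raise ValueError("stage labels do not match expression columns")
        counts = self.stages.value_counts()
        if set(counts.index) != {1, 2, 3}:
            raise ValueError("expected exactly the three stages 1, 2, 3")
        if (counts < 2).any():
            raise ValueError("need >= 2 samples per stage")


@dataclass
class CaseControlSet:
    """Expression matrix with a binary case/control label per sample."""

    expr: pd.DataFrame
    is_case: pd.Series
    name: str = ""

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.is_case.index):
            raise ValueError("condition labels do not match expression columns")
        n_case = int(self.is_case.sum())
        n_ctl = int((~self.is_case).sum())
        if n_case < 3 or n_ctl < 3:
            raise ValueError("need >= 3 cases and >= 3 controls")


@dataclass
class ReversalProportion:
    """Reversal vs monotone pattern counts within a conditioning set."""

    numerator: int  # reversal-pattern count
    denominator: int  # direction-matched monotone-pattern count
    numerator_pattern: str
    denominator_pattern: str
    n_condition: int

    @property
    def proportion(self) -> float:
        """num / (num + den); NaN when both counts are zero."""
        total = self.numerator + self.denominator
        return self.numerator / total if total else float("nan")

    @property
    def ratio(self) -> float:
        """Plain num / den; inf or NaN on a zero denominator."""
        if self.denominator == 0:
            return float("inf") if self.numerator else float("nan")
        return self.numerator / self.denominator


# ---------------------------------------------------------------------------
# Differentiation stages
# ---------------------------------------------------------------------------


def stage_trends(series: StageSeries, exact_below_n: int = 10) -> pd.DataFrame:
    """Per-gene Spearman trend table against the ordinal stage."""
    return trend_table(
        series.expr.to_numpy(dtype=float),
        series.stages.to_numpy(dtype=float),
        series.expr.index,
        exact_below_n=exact_below_n,
    )


def differentiation_up_genes(
    trends: pd.DataFrame, q_threshold: float = 0.05
) -> pd.Index:
    """Genes significantly up-regulated along the stages (q < 0.05)."""
    mask = (trends["q"] < q_threshold) & (trends["rho"] > 0)
    return trends.index[mask]


# ---------------------------------------------------------------------------
# Conditioned reversal proportions
# ---------------------------------------------------------------------------


def conditioned_reversal_proportion(
    condition_set,
    reversal_column: pd.Series,
    numerator_pattern: str = "up-down",
    denominator_pattern: str = "up-up",
) -> ReversalProportion:
    """Reversal proportion among a conditioning gene set in one dataset.

    Numerator and denominator patterns must share the developmental
    direction (up-down vs up-up, or down-up vs down-down for the
    disease analysis conditioned on down-regulation).
    """
    if numerator_pattern.split("-")[0] != denominator_pattern.split("-")[0]:
        raise ValueError("patterns must share the developmental direction")
    cond = pd.Index(condition_set)
    col = reversal_column[reversal_column.index.isin(cond)]
    return ReversalProportion(
        numerator=int((col == numerator_pattern).sum()),
        denominator=int((col == denominator_pattern).sum()),
        numerator_pattern=numerator_pattern,
        denominator_pattern=denominator_pattern,
        n_condition=len(col),
    )


def _proportions_from_table(
    condition_set, table: pd.DataFrame, numerator: str, denominator: str
) -> np.ndarray:
    return np.array(
        [
            conditioned_reversal_proportion(
                condition_set, table[name], numerator, denominator
            ).proportion
            for name in table.columns
        ]
    )


def aging_age_permutation_test(
    condition_set,
    datasets: Sequence[AgeSeriesDataset],
    n_permutations: int = 1000,
    seed: int | None = None,
    turning_age_years: float = DEFAULT_TURNING_AGE_YEARS,
    numerator_pattern: str = "up-down",
    denominator_pattern: str = "up-up",
    permute_period: str = "aging",
    engine: TrendSignEngine | None = None,
) -> dict:
    """Structured age-permutation test of conditioned reversal proportions.

    Only ``permute_period`` ages are shuffled (within source and
    period, shared across regions); the other period keeps its observed
    trends. Per dataset, the null is the permuted reversal proportion;
    the overall statistic is the number of datasets with a proportion
    strictly above 0.5, against the same joint permutations.

    Returns ``{"per_dataset": {name: PermutationResult},
    "overall": PermutationResult}``.
    """
    if engine is None:
        engine = TrendSignEngine(datasets, turning_age_years)
    table = engine.reversal_table()
    names = list(table.columns)
    observed = _proportions_from_table(
        condition_set, table, numerator_pattern, denominator_pattern
    )
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(names)))
    for b in range(n_permutations):
        maps = engine.permuted_age_maps(rng, periods=(permute_period,))
        null[b] = _proportions_from_table(
            condition_set, engine.reversal_table(maps),
            numerator_pattern, denominator_pattern,
        )
    per_dataset = {
        name: PermutationResult(float(observed[i]), null[:, i], n_permutations, seed)
        for i, name in enumerate(names)
    }
    overall = PermutationResult(
        float(np.sum(observed > 0.5)),
        np.nansum(null > 0.5, axis=1).astype(float),
        n_permutations,
        seed,
    )
    return {"per_dataset": per_dataset, "overall": overall}


# ---------------------------------------------------------------------------
# Top-N label permutations
# ---------------------------------------------------------------------------


def topn_stage_permutation_test(
    series: StageSeries,
    reversal_table: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int | None = None,
    q_threshold: float = 0.05,
    numerator_pattern: str = "up-down",
    denominator_pattern: str = "up-up",
) -> dict:
    """Stage-label permutation test of the differentiation reversal excess.

    The observed conditioning set is the significantly stage-up-regulated
    genes; per age-series dataset, N is the number of those genes whose
    developmental direction matches the reversal pair. Each replicate
    shuffles the stage labels, re-ranks all genes by the permuted stage
    correlation, and substitutes the top N genes (among genes with the
    matching developmental direction in that dataset) for the condition
    set, so null proportions come from sets of the observed size.
    With unshuffled labels the construction reproduces the observed
    proportion exactly.
    """
    trends = stage_trends(series)
    condition = differentiation_up_genes(trends, q_threshold)
    if len(condition) == 0:
        raise ValueError("no significant stage-up genes; N would be 0")
    names = list(reversal_table.columns)
    # per dataset: genes with the conditioning developmental direction
    eligible = {
        name: reversal_table.index[
            reversal_table[name].isin([numerator_pattern, denominator_pattern])
        ]
        for name in names
    }
    n_per_dataset = {
        name: int(eligible[name].isin(condition).sum()) for name in names
    }

    def _proportion(cond, name) -> float:
        return conditioned_reversal_proportion(
            cond, reversal_table[name], numerator_pattern, denominator_pattern
        ).proportion

    observed = np.array([_proportion(condition, name) for name in names])

    expr = series.expr.to_numpy(dtype=float)
    stages = series.stages.to_numpy(dtype=float)
    genes = series.expr.index
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(names)))
    for b in range(n_permutations):
        rho = spearman_rho_matrix(expr, rng.permutation(stages))
        order = genes[np.argsort(-rho, kind="stable")]
        for i, name in enumerate(names):
            n = n_per_dataset[name]
            top = order[order.isin(eligible[name])][:n]
            null[b, i] = _proportion(top, name)
    per_dataset = {
        name: PermutationResult(float(observed[i]), null[:, i], n_permutations, seed)
        for i, name in enumerate(names)
    }
    overall = PermutationResult(
        float(np.sum(observed > 0.5)),
        np.nansum(null > 0.5, axis=1).astype(float),
        n_permutations,
        seed,
    )
    return {"per_dataset": per_dataset, "overall": overall,
            "condition_set": condition, "n_per_dataset": n_per_dataset}


# ---------------------------------------------------------------------------
# Case/control (AD-style)
# ---------------------------------------------------------------------------


def case_control_signs(cc: CaseControlSet) -> pd.Series:
    """Per-gene sign of (case mean - control mean); 0 when equal."""
    expr = cc.expr.to_numpy(dtype=float)
    case = expr[:, cc.is_case.to_numpy()].mean(axis=1)
    ctl = expr[:, ~cc.is_case.to_numpy()].mean(axis=1)
    return pd.Series(np.sign(case - ctl), index=cc.expr.index)


def ad_consistent_genes(
    sets: Sequence[CaseControlSet], direction: str
) -> pd.Index:
    """Genes shifted in the same direction in every case/control cohort."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not sets:
        raise ValueError("need >= 1 case/control set")
    target = 1.0 if direction == "up" else -1.0
    genes = sets[0].expr.index
    for cc in sets[1:]:
        genes = genes.intersection(cc.expr.index)
    mask = np.ones(len(genes), dtype=bool)
    for cc in sets:
        mask &= (case_control_signs(cc).loc[genes] == target).to_numpy()
    return genes[mask]


def _shuffled(cc: CaseControlSet, rng: np.random.Generator) -> CaseControlSet:
    labels = pd.Series(
        rng.permutation(cc.is_case.to_numpy()), index=cc.is_case.index
    )
    return CaseControlSet(expr=cc.expr, is_case=labels, name=cc.name)


def ad_consistency_permutation_test(
    sets: Sequence[CaseControlSet],
    direction: str,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Label-mixing permutation test of the consistent-gene count."""
    observed = float(len(ad_consistent_genes(sets, direction)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        shuffled = [_shuffled(cc, rng) for cc in sets]
        null[b] = len(ad_consistent_genes(shuffled, direction))
    return PermutationResult(observed, null, n_permutations, seed)


def _ranked_by_consistency(
    sets: Sequence[CaseControlSet], direction: str
) -> pd.Index:
    """Genes sorted by (cohort count with the direction, mean effect)."""
    target = 1.0 if direction == "up" else -1.0
    genes = sets[0].expr.index
    for cc in sets[1:]:
        genes = genes.intersection(cc.expr.index)
    count = np.zeros(len(genes))
    effect = np.zeros(len(genes))
    for cc in sets:
        expr = cc.expr.loc[genes].to_numpy(dtype=float)
        diff = (
            expr[:, cc.is_case.to_numpy()].mean(axis=1)
            - expr[:, ~cc.is_case.to_numpy()].mean(axis=1)
        )
        count += np.sign(diff) == target
        effect += target * diff
    order = np.lexsort((-effect, -count))
    return genes[order]


def topn_case_control_permutation_test(
    sets: Sequence[CaseControlSet],
    statistic: Callable[[pd.Index, pd.Index], float],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Label-mixing permutation test with top-N surrogate gene sets.

    ``statistic`` receives the (up-consistent, down-consistent) gene
    sets. Observed sets are the unanimously shifted genes; their sizes
    N_up and N_down are held fixed in every replicate, where labels are
    shuffled within each cohort and the top N genes of the
    consistency-then-effect ranking stand in for the consistent sets.
    With unshuffled labels the top-N sets equal the consistent sets, so
    the observed statistic is reproduced exactly.
    """
    up = ad_consistent_genes(sets, "up")
    down = ad_consistent_genes(sets, "down")
    n_up, n_down = len(up), len(down)
    if n_up == 0 and n_down == 0:
        raise ValueError("no consistent genes; N would be 0")
    observed = float(statistic(up, down))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        shuffled = [_shuffled(cc, rng) for cc in sets]
        up_b = _ranked_by_consistency(shuffled, "up")[:n_up]
        down_b = _ranked_by_consistency(shuffled, "down")[:n_down]
        null[b] = statistic(up_b, down_b)
    return PermutationResult(observed, null, n_permutations, seed)


def dev_ad_overlap_proportion(
    dev_up, ad_up, ad_down
) -> dict:
    """Share of development-up genes that are down- rather than up-in-AD.

    Returns both the proportion |dev-up & ad-down| / (|dev-up & ad-down|
    + |dev-up & ad-up|) and the plain ratio of the two intersections.
    """
    dev_up = pd.Index(dev_up)
    n_down = len(dev_up.intersection(pd.Index(ad_down)))
    n_up = len(dev_up.intersection(pd.Index(ad_up)))
    total = n_down + n_up
    return {
        "n_dev_up_ad_down": n_down,
        "n_dev_up_ad_up": n_up,
        "proportion": n_down / total if total else float("nan"),
        "ratio": (n_down / n_up) if n_up else (float("inf") if n_down else float("nan")),
    }
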