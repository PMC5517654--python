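"""Synthetic multi-source brain age-series data with planted ground truth.

The generator emulates the structure of real postmortem brain
transcriptome age-series collections: a few data sources (laboratories),
each profiling several brain regions of the *same* individuals, with
individual ages spanning the whole postnatal lifespan. Genes are planted
with monotone rank-linear trends within each period (development before
the turning age, aging after), following one of four direction-pair
patterns (up-down, down-up, up-up, down-down) or no trend at all.
Noise is Gaussian and, by default, larger in aging than in development.

Ages are drawn uniformly on the fourth-root-of-days scale, which spreads
individuals evenly across the lifespan, and trend signals are linear in
the within-period age rank so that rank-based downstream statistics see
exactly the planted effect sizes.

Auxiliary generators produce cell-type signature/mixture data, gene-set
collections with planted conditional enrichment, three-stage neuronal
differentiation series, and case/control (AD-style) cohorts whose
disease signal optionally overlaps the planted aging reversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import AgeSeriesDataset, years_to_days

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_age_series",
    "generate_cell_type_data",
    "generate_gene_sets",
    "generate_differentiation_series",
    "generate_case_control",
]

PATTERN_SIGNS = {
    "up-down": (1, -1),
    "down-up": (-1, 1),
    "up-up": (1, 1),
    "down-down": (-1, -1),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic age-series study.

    Defaults describe a minutes-scale study: 2 sources with 2 and 3
    brain regions (5 datasets), 20 development + 25 aging individuals
    per source, 2,000 genes, unit effect sizes on the standardized
    scale, and aging noise twice the development noise.
    """

    n_sources: int = 2
    regions_per_source: int | tuple[int, ...] = (2, 3)
    n_individuals_dev: int = 20
    n_individuals_aging: int = 25
    n_genes: int = 2000
    fraction_updown: float = 0.05
    fraction_downup: float = 0.05
    fraction_monotonic_up: float = 0.05
    fraction_monotonic_down: float = 0.05
    effect_size_dev: float = 1.0
    effect_size_aging: float = 1.0
    noise_sd_dev: float = 0.5
    noise_sd_aging: float = 1.0
    turning_age_years: float = 20.0
    max_age_years: float = 98.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(f < 0 or f > 1 for f in fr.values()):
            raise ValueError("pattern fractions must lie in [0, 1]")
        if sum(fr.values()) > 1 + 1e-12:
            raise ValueError("pattern fractions sum above 1")
        if self.noise_sd_dev <= 0 or self.noise_sd_aging <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.n_individuals_dev < 3 or self.n_individuals_aging < 3:
            raise ValueError("each period needs >= 3 individuals")
        if self.n_sources < 1 or self.n_genes < 1:
            raise ValueError("need >= 1 source and >= 1 gene")
        for r in self.regions_per_source_tuple:
            if r < 1:
                raise ValueError("each source needs >= 1 region")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "up-down": self.fraction_updown,
            "down-up": self.fraction_downup,
            "up-up": self.fraction_monotonic_up,
            "down-down": self.fraction_monotonic_down,
        }

    @property
    def regions_per_source_tuple(self) -> tuple[int, ...]:
        r = self.regions_per_source
        if isinstance(r, int):
            return (r,) * self.n_sources
        if len(r) != self.n_sources:
            raise ValueError("regions_per_source length must equal n_sources")
        return tuple(r)


@dataclass
class GroundTruth:
    """Planted signal of one simulation.

    ``patterns`` labels every gene exactly once with its planted trend
    pattern ("null" = no age effect). Auxiliary generators fill the
    remaining fields.
    """

    patterns: pd.Series
    enriched_sets: list[str] = field(default_factory=list)
    mixing_weights: pd.DataFrame | None = None
    diff_direction: pd.Series | None = None
    ad_direction: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.patterns.index

    def genes_with_pattern(self, pattern: str) -> pd.Index:
        return self.patterns.index[self.patterns == pattern]


# ---------------------------------------------------------------------------
# Age series
# ---------------------------------------------------------------------------


def _assign_patterns(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")
    labels = np.full(config.n_genes, "null", dtype=object)
    start = 0
    for pattern, frac in config.fractions.items():
        k = int(round(frac * config.n_genes))
        labels[start:start + k] = pattern
        start += k
    rng.shuffle(labels)
    return pd.Series(labels, index=genes, name="pattern")


def _draw_ages_days(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Ages uniform on the fourth-root-of-days scale, both periods filled."""
    cut4 = years_to_days(config.turning_age_years) ** 0.25
    max4 = years_to_days(config.max_age_years) ** 0.25
    dev = rng.uniform(0, cut4, size=config.n_individuals_dev) ** 4
    aging = rng.uniform(cut4, max4, size=config.n_individuals_aging) ** 4
    return np.concatenate([dev, aging])


def _rank_signal(ages: np.ndarray) -> np.ndarray:
    """Within-period signal, linear in age rank, spanning [-1, 1]."""
    order = np.argsort(np.argsort(ages))
    n = len(ages)
    if n == 1:
        return np.zeros(1)
    return 2.0 * order / (n - 1) - 1.0


def generate_age_series(
    config: SimulationConfig,
) -> tuple[list[AgeSeriesDataset], GroundTruth]:
    """Simulate all datasets of the study with shared individuals.

    Every region dataset of a source contains the same individuals at
    the same ages; expression noise is independent between regions.
    Identical configs (including the seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    patterns = _assign_patterns(config, rng)
    genes = patterns.index
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))

    sign_dev = np.zeros(len(genes))
    sign_aging = np.zeros(len(genes))
    for pattern, (sd_, sa_) in PATTERN_SIGNS.items():
        mask = (patterns == pattern).to_numpy()
        sign_dev[mask] = sd_
        sign_aging[mask] = sa_

    cut = years_to_days(config.turning_age_years)
    datasets: list[AgeSeriesDataset] = []
    for s, n_regions in enumerate(config.regions_per_source_tuple):
        source = f"source{s + 1}"
        ages = _draw_ages_days(config, rng)
        individuals = np.array([f"{source}_i{k:03d}" for k in range(len(ages))])
        in_dev = ages < cut
        signal_scale = np.zeros(len(ages))
        signal_scale[in_dev] = config.effect_size_dev * _rank_signal(ages[in_dev])
        signal_scale[~in_dev] = config.effect_size_aging * _rank_signal(ages[~in_dev])
        # gene x sample planted signal (sign depends on gene pattern and period)
        sign_per_sample = np.where(in_dev[None, :], sign_dev[:, None], sign_aging[:, None])
        signal = sign_per_sample * signal_scale[None, :]
        noise_sd = np.where(in_dev, config.noise_sd_dev, config.noise_sd_aging)
        for r in range(n_regions):
            region = f"region{r + 1}"
            noise = rng.normal(0.0, 1.0, size=signal.shape) * noise_sd[None, :]
            expr = baseline[:, None] + signal + noise
            samples = [f"{source}.{region}.{ind}" for ind in individuals]
            meta = pd.DataFrame(
                {
                    "individual_id": individuals,
                    "age_days": ages,
                    "source": source,
                    "region": region,
                },
                index=pd.Index(samples, name="sample_id"),
            )
            datasets.append(
                AgeSeriesDataset(
                    expr=pd.DataFrame(expr, index=genes, columns=samples),
                    meta=meta,
                    name=f"{source}.{region}",
                )
            )
    return datasets, GroundTruth(patterns=patterns)


# ---------------------------------------------------------------------------
# Cell types
# ---------------------------------------------------------------------------

_CELL_TYPE_NAMES = (
    "neuron", "astrocyte", "oligodendrocyte", "opc", "endothelial",
    "microglia", "fetal_quiescent", "fetal_replicating",
)


def generate_cell_type_data(
    config: SimulationConfig,
    n_cell_types: int = 5,
    n_samples: int = 50,
    noise_sd: float = 0.1,
    neuronal_decline: bool = True,
) -> tuple[pd.DataFrame, AgeSeriesDataset, GroundTruth]:
    """Cell-type signature profiles and bulk mixtures with known weights.

    Each bulk sample is a non-negative linear combination of the
    signature profiles plus Gaussian noise. With ``neuronal_decline``
    the first cell type's ("neuron") weight falls linearly with age
    rank, emulating shrinking neuronal contribution to the tissue
    mRNA pool.
    """
    if n_cell_types < 2:
        raise ValueError("need >= 2 cell types")
    rng = np.random.default_rng(config.seed + 1)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")
    names = [
        _CELL_TYPE_NAMES[i] if i < len(_CELL_TYPE_NAMES) else f"celltype{i + 1}"
        for i in range(n_cell_types)
    ]
    signature = pd.DataFrame(
        rng.normal(config.baseline_mean, config.baseline_sd,
                   size=(len(genes), n_cell_types)),
        index=genes,
        columns=names,
    )
    max4 = years_to_days(config.max_age_years) ** 0.25
    ages = np.sort(rng.uniform(0, max4, size=n_samples) ** 4)
    if neuronal_decline:
        ranks = np.arange(n_samples) / max(1, n_samples - 1)
        w_neuron = 0.75 - 0.4 * ranks
    else:
        w_neuron = np.full(n_samples, 0.55)
    other = rng.dirichlet(np.full(n_cell_types - 1, 5.0), size=n_samples)
    weights = np.column_stack([w_neuron, other * (1 - w_neuron)[:, None]])
    bulk = signature.to_numpy() @ weights.T
    bulk += rng.normal(0.0, noise_sd, size=bulk.shape)
    samples = pd.Index([f"mix.s{k:03d}" for k in range(n_samples)], name="sample_id")
    meta = pd.DataFrame(
        {
            "individual_id": [f"mix_i{k:03d}" for k in range(n_samples)],
            "age_days": ages,
            "source": "mixture",
            "region": "bulk",
        },
        index=samples,
    )
    mixture = AgeSeriesDataset(
        expr=pd.DataFrame(bulk, index=genes, columns=samples),
        meta=meta,
        name="mixture.bulk",
    )
    truth = GroundTruth(
        patterns=pd.Series("null", index=genes, name="pattern"),
        mixing_weights=pd.DataFrame(weights, index=samples, columns=names),
    )
    return signature, mixture, truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def generate_gene_sets(
    truth: GroundTruth,
    n_sets: int = 200,
    planted_enriched: int = 10,
    set_size_range: tuple[int, int] = (10, 50),
    enriched_updown_fraction: float = 0.6,
    seed: int = 0,
):
    """Gene-set collection with planted conditional reversal enrichment.

    Planted sets draw ``enriched_updown_fraction`` of their members from
    planted up-down genes and the rest from genes that are not up-up, so
    the up-down versus up-up odds ratio exceeds one whenever the planted
    trends are recovered. Background sets sample genes uniformly. One
    exact duplicate of a background set is appended to exercise
    deduplication.

    Returns ``(sets, truth)`` where ``sets`` maps set name to a list of
    member genes and ``truth`` carries the planted set names.
    """
    if planted_enriched > n_sets:
        raise ValueError("planted_enriched exceeds n_sets")
    lo, hi = set_size_range
    genes = truth.genes
    if hi > len(genes):
        raise ValueError("set sizes exceed the gene universe")
    rng = np.random.default_rng(seed)
    updown = truth.genes_with_pattern("up-down").to_numpy()
    not_upup = genes[truth.patterns != "up-up"].to_numpy()
    sets: dict[str, list[str]] = {}
    enriched_names = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"set{i:04d}"
        if i < planted_enriched:
            if len(updown) == 0:
                raise ValueError("cannot plant enrichment without up-down genes")
            k_ud = min(len(updown), max(1, int(round(enriched_updown_fraction * size))))
            members = list(rng.choice(updown, size=k_ud, replace=False))
            rest_pool = np.setdiff1d(not_upup, members)
            k_rest = min(size - k_ud, len(rest_pool))
            members += list(rng.choice(rest_pool, size=k_rest, replace=False))
            name = f"enriched{i:04d}"
            enriched_names.append(name)
        else:
            members = list(rng.choice(genes.to_numpy(), size=size, replace=False))
        sets[name] = sorted(members)
    if n_sets > planted_enriched:
        first_bg = f"set{planted_enriched:04d}"
        sets[first_bg + "_dup"] = list(sets[first_bg])
    truth = replace_truth(truth, enriched_sets=enriched_names)
    return sets, truth


def replace_truth(truth: GroundTruth, **kwargs) -> GroundTruth:
    """Copy of a GroundTruth with some fields replaced."""
    return replace(truth, **kwargs)


# ---------------------------------------------------------------------------
# Differentiation series
# ---------------------------------------------------------------------------


def generate_differentiation_series(
    truth: GroundTruth,
    n_per_stage: int = 4,
    fraction_diff_up: float = 0.1,
    overlap_with_updown: float = 0.0,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Three-stage (iPSC, neurosphere, neuron) differentiation series.

    Planted differentiation-up genes gain ``effect_size`` per stage. A
    fraction ``overlap_with_updown`` of them is drawn from the planted
    up-down aging genes (to emulate shared identity-establishment
    genes); the rest come from null genes.

    Returns ``(stage_series, truth)`` with ``truth.diff_direction`` set.
    """
    from .cross_studies import StageSeries

    if n_per_stage < 2:
        raise ValueError("need >= 2 samples per stage")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    n_diff = int(round(fraction_diff_up * len(genes)))
    updown = truth.genes_with_pattern("up-down").to_numpy()
    null_genes = truth.genes_with_pattern("null").to_numpy()
    k_overlap = min(len(updown), int(round(overlap_with_updown * n_diff)))
    members = list(rng.choice(updown, size=k_overlap, replace=False))
    pool = np.setdiff1d(null_genes, members)
    members += list(rng.choice(pool, size=min(n_diff - k_overlap, len(pool)),
                               replace=False))
    diff_up = pd.Index(members)

    stages = np.repeat([1, 2, 3], n_per_stage)
    samples = pd.Index(
        [f"diff.stage{s}.r{r}" for s in (1, 2, 3) for r in range(n_per_stage)],
        name="sample_id",
    )
    baseline = rng.normal(8.0, 2.0, size=len(genes))
    expr = baseline[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), len(stages)))
    is_diff = genes.isin(diff_up)
    expr[is_diff] += effect_size * (stages[None, :] - 2)
    series = StageSeries(
        expr=pd.DataFrame(expr, index=genes, columns=samples),
        stages=pd.Series(stages, index=samples, name="stage"),
    )
    direction = pd.Series("none", index=genes, name="diff_direction")
    direction[diff_up] = "up"
    return series, replace_truth(truth, diff_direction=direction)


# ---------------------------------------------------------------------------
# Case/control (AD-style)
# ---------------------------------------------------------------------------


def generate_case_control(
    truth: GroundTruth,
    n_cases: int = 10,
    n_controls: int = 10,
    overlap_with_aging: float = 0.5,
    fraction_ad_down: float = 0.05,
    fraction_ad_up: float = 0.05,
    shift: float = 1.0,
    noise_sd: float = 0.5,
    n_datasets: int = 2,
    seed: int = 0,
):
    """Case/control cohorts with disease shifts overlapping aging trends.

    Planted AD-down genes are shifted down in cases (AD-up genes up); a
    fraction ``overlap_with_aging`` of the AD-down genes coincides with
    planted up-down aging genes, the rest (and all AD-up genes) are
    drawn from null genes.

    Returns ``(case_control_sets, truth)`` with ``truth.ad_direction``.
    """
    from .cross_studies import CaseControlSet

    if n_cases < 3 or n_controls < 3:
        raise ValueError("need >= 3 cases and >= 3 controls")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    n_down = int(round(fraction_ad_down * len(genes)))
    n_up = int(round(fraction_ad_up * len(genes)))
    updown = truth.genes_with_pattern("up-down").to_numpy()
    null_genes = truth.genes_with_pattern("null").to_numpy()
    k_overlap = min(len(updown), int(round(overlap_with_aging * n_down)))
    down_members = list(rng.choice(updown, size=k_overlap, replace=False))
    pool = np.setdiff1d(null_genes, down_members)
    down_members += list(
        rng.choice(pool, size=min(n_down - k_overlap, len(pool)), replace=False)
    )
    pool = np.setdiff1d(null_genes, down_members)
    up_members = list(rng.choice(pool, size=min(n_up, len(pool)), replace=False))

    direction = pd.Series("none", index=genes, name="ad_direction")
    direction[pd.Index(down_members)] = "down"
    direction[pd.Index(up_members)] = "up"
    delta = np.zeros(len(genes))
    delta[genes.isin(down_members)] = -shift
    delta[genes.isin(up_members)] = shift

    sets = []
    for d in range(n_datasets):
        baseline = rng.normal(8.0, 2.0, size=len(genes))
        n_total = n_cases + n_controls
        is_case = np.array([True] * n_cases + [False] * n_controls)
        expr = baseline[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n_total))
        expr[:, is_case] += delta[:, None]
        samples = pd.Index(
            [f"ad{d + 1}.{'case' if c else 'ctl'}{k:02d}"
             for k, c in enumerate(is_case)],
            name="sample_id",
        )
        sets.append(
            CaseControlSet(
                expr=pd.DataFrame(expr, index=genes, columns=samples),
                is_case=pd.Series(is_case, index=samples, name="is_case"),
                name=f"ad{d + 1}",
            )
        )
    return sets, replace_truth(truth, ad_direction=direction)


# ---------------------------------------------------------------------------
# Ground-truth IO
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the per-gene truth labels as a tab-delimited table."""
    out = pd.DataFrame({"pattern": truth.patterns})
    if truth.diff_direction is not None:
        out["diff_direction"] = truth.diff_direction
    if truth.ad_direction is not None:
        out["ad_direction"] = truth.ad_direction
    out.to_csv(path, sep="\t", index_label="gene_id")
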