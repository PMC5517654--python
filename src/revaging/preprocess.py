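"""Loading, normalization and period-splitting of age-series expression data.

An age-series dataset is a gene x sample log2 expression matrix with a
per-sample metadata table carrying the individual identity, the age (in
days), the data source (laboratory/experiment) and the brain region.
Datasets from the same source share individuals across regions, which is
the dependence structure the structured permutation test must respect.

The analysis splits each dataset at a "turning age" (default 20 years)
into a postnatal-development part (ages strictly below the turning age)
and an aging part (ages at or above it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("revaging")

DAYS_PER_YEAR = 365.25
#: Default age (years) separating postnatal development from aging.
DEFAULT_TURNING_AGE_YEARS = 20.0

REQUIRED_META_COLUMNS = ("individual_id", "age_days", "source", "region")


def years_to_days(years: float) -> float:
    return float(years) * DAYS_PER_YEAR


def days_to_years(days: float) -> float:
    return float(days) / DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class AgeSeriesDataset:
    """One brain-region expression dataset with sample metadata.

    Parameters
    ----------
    expr
        Gene x sample matrix (log2 scale after normalization). Row index
        holds gene IDs, columns hold sample IDs.
    meta
        Sample metadata indexed by sample ID with columns
        ``individual_id``, ``age_days``, ``source`` and ``region``.
    name
        Dataset label, conventionally ``"<source>.<region>"``.
    """

    expr: pd.DataFrame
    meta: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata lacks required columns: {missing}")
        if not self.expr.columns.equals(self.meta.index):
            if set(self.expr.columns) != set(self.meta.index):
                raise ValueError("expression columns and metadata rows disagree")
            self.meta = self.meta.loc[self.expr.columns]
        if self.expr.index.has_duplicates:
            raise ValueError("duplicate gene IDs; summarize features first")
        if (self.meta["age_days"] < 0).any():
            raise ValueError("negative ages")
        if self.expr.isna().any().any():
            raise ValueError("missing expression values; handle at load time")
        if not self.name:
            src = self.meta["source"].iloc[0]
            reg = self.meta["region"].iloc[0]
            self.name = f"{src}.{reg}"

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def ages_days(self) -> pd.Series:
        return self.meta["age_days"]

    @property
    def ages_years(self) -> pd.Series:
        return self.meta["age_days"] / DAYS_PER_YEAR

    @property
    def source(self) -> str:
        return str(self.meta["source"].iloc[0])

    def subset_samples(self, sample_ids) -> "AgeSeriesDataset":
        return AgeSeriesDataset(
            expr=self.expr[list(sample_ids)],
            meta=self.meta.loc[list(sample_ids)],
            name=self.name,
        )

    def with_ages(self, age_days: pd.Series) -> "AgeSeriesDataset":
        """Return a copy with replaced ages (used by the permutation null)."""
        meta = self.meta.copy()
        meta["age_days"] = age_days.reindex(meta.index)
        return AgeSeriesDataset(expr=self.expr, meta=meta, name=self.name)


@dataclass
class SubDataset:
    """One period (development or aging) of one dataset."""

    dataset: AgeSeriesDataset
    period: str  # "development" | "aging"
    turning_age_years: float = DEFAULT_TURNING_AGE_YEARS

    def __post_init__(self) -> None:
        if self.period not in ("development", "aging"):
            raise ValueError(f"unknown period {self.period!r}")
        cut = years_to_days(self.turning_age_years)
        ages = self.dataset.ages_days.to_numpy()
        if self.period == "development" and (ages >= cut).any():
            raise ValueError("development sub-dataset holds ages >= turning age")
        if self.period == "aging" and (ages < cut).any():
            raise ValueError("aging sub-dataset holds ages < turning age")

    @property
    def expr(self) -> pd.DataFrame:
        return self.dataset.expr

    @property
    def meta(self) -> pd.DataFrame:
        return self.dataset.meta

    @property
    def ages_days(self) -> pd.Series:
        return self.dataset.ages_days

    @property
    def name(self) -> str:
        return f"{self.dataset.name}.{self.period}"


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_matrix(path) -> pd.DataFrame:
    """Read a tab-delimited gene x sample matrix (first column = gene IDs)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index.name = "sample_id"
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def load_dataset(matrix_path, meta_path, name: str = "") -> AgeSeriesDataset:
    """Load matrix + metadata; rows with any missing value are dropped."""
    expr = read_matrix(matrix_path)
    meta = read_metadata(meta_path)
    n_missing = int(expr.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d genes with missing values", n_missing)
        expr = expr.dropna(axis=0)
    return AgeSeriesDataset(expr=expr, meta=meta, name=name)


def write_dataset(ds: AgeSeriesDataset, matrix_path, meta_path) -> None:
    write_matrix(ds.expr, matrix_path)
    write_metadata(ds.meta, meta_path)


# ---------------------------------------------------------------------------
# Normalization and summarization
# ---------------------------------------------------------------------------


def log2_quantile_normalize(
    matrix: pd.DataFrame, already_logged: bool = False
) -> pd.DataFrame:
    """log2-transform and quantile-normalize a gene x sample matrix.

    After normalization every sample column shares the identical sorted
    value vector: the across-sample mean of the sorted columns. Tied
    values within a column receive the mean of the quantile values their
    midrank spans.
    """
    x = matrix.to_numpy(dtype=float)
    if not already_logged:
        if (x <= 0).any():
            raise ValueError("non-positive values; pass already_logged=True "
                             "if the matrix is on log scale")
        x = np.log2(x)
    n_genes, n_samples = x.shape
    mean_quantiles = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        ranks = rankdata(x[:, j], method="average")  # midranks for ties
        # fractional ranks interpolate between adjacent mean quantiles
        out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), mean_quantiles)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def summarize_features_to_genes(matrix: pd.DataFrame, feature_to_gene) -> pd.DataFrame:
    """Collapse feature (probe-set) rows to one row per gene by the mean.

    ``feature_to_gene`` maps feature IDs to gene IDs; a mapping of a
    feature to more than one distinct gene is ambiguous and the feature
    is removed before averaging. Features without a mapping are dropped.
    """
    if isinstance(feature_to_gene, dict):
        pairs = [(f, g) for f, gs in feature_to_gene.items()
                 for g in (gs if isinstance(gs, (list, tuple, set)) else [gs])]
    else:
        pairs = [tuple(p) for p in feature_to_gene]
    mapping = pd.DataFrame(pairs, columns=["feature", "gene"]).drop_duplicates()
    genes_per_feature = mapping.groupby("feature")["gene"].nunique()
    unambiguous = genes_per_feature.index[genes_per_feature == 1]
    mapping = mapping[mapping["feature"].isin(unambiguous)]
    mapping = mapping[mapping["feature"].isin(matrix.index)]
    if mapping.empty:
        raise ValueError("no feature maps unambiguously to a gene")
    sub = matrix.loc[mapping["feature"]]
    gene_of = mapping.set_index("feature")["gene"]
    out = sub.groupby(gene_of.reindex(sub.index).to_numpy()).mean()
    out.index.name = matrix.index.name
    return out


def filter_low_expression(matrix: pd.DataFrame, mean_threshold: float) -> pd.DataFrame:
    """Keep genes whose row mean is >= ``mean_threshold`` (linear scale)."""
    keep = matrix.mean(axis=1) >= mean_threshold
    if not keep.any():
        raise ValueError("threshold removes every gene")
    return matrix.loc[keep]


# ---------------------------------------------------------------------------
# Period split
# ---------------------------------------------------------------------------


def split_periods(
    dataset: AgeSeriesDataset,
    turning_age_years: float = DEFAULT_TURNING_AGE_YEARS,
    min_individuals: int = 3,
) -> tuple[SubDataset, SubDataset]:
    """Split a dataset into development (< turning age) and aging (>=).

    A sample at exactly the turning age belongs to aging. Raises if
    either period holds fewer than ``min_individuals`` individuals.
    """
    cut = years_to_days(turning_age_years)
    ages = dataset.ages_days
    dev_samples = ages.index[ages < cut]
    aging_samples = ages.index[ages >= cut]
    for label, samples in (("development", dev_samples), ("aging", aging_samples)):
        n_ind = dataset.meta.loc[samples, "individual_id"].nunique()
        if n_ind < min_individuals:
            raise ValueError(
                f"{label} period of {dataset.name!r} holds {n_ind} individuals; "
                f"need >= {min_individuals} for rank correlation"
            )
    dev = SubDataset(dataset.subset_samples(dev_samples), "development", turning_age_years)
    aging = SubDataset(dataset.subset_samples(aging_samples), "aging", turning_age_years)
    return dev, aging


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_scores(matrix: pd.DataFrame, n_components: int = 2):
    """PCA of observations (columns) over features (rows).

    Rows are centered (each feature to mean zero, no scaling) and the
    column observations are projected on the principal axes. Each
    component is oriented so its largest-magnitude loading is positive.

    Returns
    -------
    scores : DataFrame (observation x component)
    explained : ndarray of explained-variance fractions
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    x = matrix.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("constant matrix has no principal components")
    # observations are columns: SVD of the (obs x feature) centered matrix
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    n_components = min(n_components, len(s))
    var = s**2
    explained = var / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    for k in range(n_components):
        loading = vt[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        explained[:n_components],
    )


def flag_pca_outliers(matrix: pd.DataFrame, n_sd: float = 4.0) -> list:
    """Report (never remove) observations beyond ``n_sd`` SD on PC1/PC2."""
    scores, _ = pca_scores(matrix, n_components=min(2, matrix.shape[1]))
    z = (scores - scores.mean()) / scores.std(ddof=1)
    flagged = scores.index[(z.abs() > n_sd).any(axis=1)]
    return list(flagged)
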