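"""Per-gene age-expression trends and their comparison across sub-datasets.

Age-related expression change is measured per gene as the Spearman rank
correlation (rho) of expression with age in days, separately within each
period (development or aging) of each dataset. P-values are adjusted by
the Benjamini-Yekutieli procedure, which controls the FDR under
arbitrary dependence among genes. Trend profiles are then compared
across sub-datasets by correlating the rho vectors over shared genes.
"""

from __future__ import annotations

from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .preprocess import SubDataset

__all__ = [
    "normalized_ranks",
    "spearman_rho_matrix",
    "trend_table",
    "age_expression_trends",
    "benjamini_yekutieli",
    "compare_trends",
    "median_within_between",
]


# ---------------------------------------------------------------------------
# Fast rank-correlation primitives
# ---------------------------------------------------------------------------


def normalized_ranks(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Midranks centered and scaled to unit norm along ``axis``.

    The dot product of two such vectors is the Spearman correlation of
    the originals (ties by midranks). A constant vector maps to zeros,
    so correlations against it are 0 rather than undefined.
    """
    r = rankdata(x, method="average", axis=axis)
    r = r - np.mean(r, axis=axis, keepdims=True)
    norm = np.linalg.norm(r, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, r / np.where(norm == 0, 1.0, norm), 0.0)
    return out


def spearman_rho_matrix(expr: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Spearman rho of each expression row against the age vector."""
    gene_r = normalized_ranks(expr, axis=1)
    age_r = normalized_ranks(ages)
    return gene_r @ age_r


def _exact_spearman_pvalues(expr: np.ndarray, ages: np.ndarray,
                            rho: np.ndarray) -> np.ndarray:
    """Two-sided exact permutation p-values for small samples.

    Enumerates all orderings of the age vector; the null for every gene
    is computed jointly as one matrix product per permutation chunk.
    """
    n = len(ages)
    gene_r = normalized_ranks(expr, axis=1)
    # ranks of a permuted vector are the permuted ranks, so rank once
    base = normalized_ranks(ages)
    idx = np.array(list(_permutations(range(n))))
    perm_ranks = base[idx]  # (n!, n)
    obs = np.abs(rho)[:, None]
    count = np.zeros(expr.shape[0], dtype=np.int64)
    chunk = max(1, int(2_000_000 / max(1, expr.shape[0])))
    for start in range(0, perm_ranks.shape[0], chunk):
        null = gene_r @ perm_ranks[start:start + chunk].T  # genes x chunk
        count += (np.abs(null) >= obs - 1e-12).sum(axis=1)
    return count / perm_ranks.shape[0]


def _t_approx_spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


# ---------------------------------------------------------------------------
# Trend tables
# ---------------------------------------------------------------------------


def trend_table(
    expr: np.ndarray, covariate: np.ndarray, index: pd.Index,
    exact_below_n: int = 10,
) -> pd.DataFrame:
    """Spearman trend table of expression rows against a covariate.

    Returns a DataFrame indexed by ``index`` with columns ``rho``
    (Spearman correlation), ``p`` (two-sided), ``q`` (Benjamini-
    Yekutieli adjusted across all rows) and ``direction`` in
    {"up", "down", "flat"}.

    Constant rows have no defined correlation; they are reported as
    rho 0, p 1, direction "flat". P-values use the t-approximation for
    n >= ``exact_below_n`` samples and exact permutation enumeration
    below that.
    """
    expr = np.asarray(expr, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    n = len(covariate)
    if n < 3:
        raise ValueError("need >= 3 samples for a rank correlation")
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant; trends are undefined")
    rho = spearman_rho_matrix(expr, covariate)
    constant = np.ptp(expr, axis=1) == 0
    if n >= exact_below_n:
        p = _t_approx_spearman_pvalues(rho, n)
    else:
        p = _exact_spearman_pvalues(expr, covariate, rho)
    rho[constant] = 0.0
    p[constant] = 1.0
    p = np.clip(p, 0.0, 1.0)
    q = benjamini_yekutieli(p)
    direction = np.where(rho > 0, "up", np.where(rho < 0, "down", "flat"))
    return pd.DataFrame(
        {"rho": rho, "p": p, "q": q, "direction": direction}, index=index
    )


def age_expression_trends(sub: SubDataset, exact_below_n: int = 10) -> pd.DataFrame:
    """Per-gene Spearman trend table of expression vs age for one sub-dataset.

    See :func:`trend_table` for the column contract; the BY adjustment
    is applied across all genes of this sub-dataset.
    """
    return trend_table(
        sub.expr.to_numpy(dtype=float),
        sub.ages_days.to_numpy(dtype=float),
        sub.expr.index,
        exact_below_n=exact_below_n,
    )


def benjamini_yekutieli(p) -> np.ndarray:
    """BY step-up FDR adjustment, valid under arbitrary dependence.

    q_(i) = min_{j >= i} min(1, m * c(m) * p_(j) / j) over the ordered
    p-values, with c(m) = sum_{k=1..m} 1/k.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = m * c_m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Cross-sub-dataset comparison
# ---------------------------------------------------------------------------


def compare_trends(tables: dict[str, pd.DataFrame] | list[pd.DataFrame]):
    """Spearman correlations of rho vectors between every pair of tables.

    Each pair is correlated over the genes shared by the two tables.

    Returns
    -------
    corr : DataFrame, symmetric with unit diagonal
    counts : DataFrame of shared-gene counts per pair
    """
    if isinstance(tables, list):
        tables = {f"table{i}": t for i, t in enumerate(tables)}
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need >= 2 trend tables")
    k = len(names)
    corr = np.eye(k)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        counts[i, i] = len(tables[names[i]])
    for i in range(k):
        for j in range(i + 1, k):
            a, b = tables[names[i]], tables[names[j]]
            shared = a.index.intersection(b.index)
            if len(shared) < 2:
                raise ValueError(
                    f"pair ({names[i]}, {names[j]}) shares "
                    f"{len(shared)} genes; need >= 2"
                )
            r, _ = stats.spearmanr(a.loc[shared, "rho"], b.loc[shared, "rho"])
            corr[i, j] = corr[j, i] = r
            counts[i, j] = counts[j, i] = len(shared)
    return (
        pd.DataFrame(corr, index=names, columns=names),
        pd.DataFrame(counts, index=names, columns=names),
    )


def median_within_between(corr: pd.DataFrame, period_labels: dict[str, str]) -> dict:
    """Medians of within-development, within-aging and between-period cells.

    ``period_labels`` maps each matrix label to "development" or
    "aging". Within-group medians are over off-diagonal upper-triangle
    cells; the between median is over all development x aging cells.
    """
    labels = [period_labels[name] for name in corr.index]
    dev_idx = [i for i, l in enumerate(labels) if l == "development"]
    ag_idx = [i for i, l in enumerate(labels) if l == "aging"]
    x = corr.to_numpy()

    def _within(idx):
        cells = [x[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]]
        if not cells:
            raise ValueError("a period group has no off-diagonal cells")
        return float(np.median(cells))

    between = [x[i, j] for i in dev_idx for j in ag_idx]
    if not between:
        raise ValueError("no between-period cells")
    return {
        "within_development": _within(dev_idx),
        "within_aging": _within(ag_idx),
        "between": float(np.median(between)),
    }
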