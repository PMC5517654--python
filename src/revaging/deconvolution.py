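"""Linear-regression deconvolution of bulk samples into cell-type parts.

Each bulk sample's expression profile Z is regressed on the cell-type
signature profiles zeta (per-cell-type mean expression over replicates):

    Z_sample = alpha + beta_1 * zeta_1 + ... + beta_K * zeta_K + eps

by ordinary least squares over the genes shared between the bulk matrix
and the signature matrix. The coefficients beta estimate the relative
contribution of each cell type's transcriptome to the sample; they are
deliberately unconstrained (no non-negativity, no sum-to-one), a plain
regression rather than a constrained deconvolution. Age trends of the
contributions are summarized by the Spearman correlation of each
coefficient with sample age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import AgeSeriesDataset
from .trajectories import spearman_rho_matrix

logger = logging.getLogger("revaging")

__all__ = ["DeconvolutionResult", "fit_contributions", "contribution_age_trend"]


@dataclass
class DeconvolutionResult:
    """Per-sample regression coefficients and residual summary."""

    intercepts: pd.Series  # alpha per sample
    coefficients: pd.DataFrame  # sample x cell type (beta)
    residual_variance: pd.Series  # var(eps) per sample
    n_shared_genes: int
    condition_number: float

    def normalized_coefficients(self) -> pd.DataFrame:
        """Reporting-only view beta / sum(beta) per sample."""
        total = self.coefficients.sum(axis=1)
        return self.coefficients.div(total, axis=0)


def fit_contributions(
    bulk: AgeSeriesDataset | pd.DataFrame,
    signatures: pd.DataFrame,
    min_shared_genes: int = 50,
) -> DeconvolutionResult:
    """OLS fit of every bulk sample on the cell-type signatures.

    Both matrices are expected on the log2 quantile-normalized scale.
    The fit is restricted to genes present in both; fewer than
    ``min_shared_genes`` shared genes triggers a warning and collinear
    signatures are flagged with the design condition number.
    """
    expr = bulk.expr if isinstance(bulk, AgeSeriesDataset) else bulk
    shared = expr.index.intersection(signatures.index)
    n_types = signatures.shape[1]
    if len(shared) < n_types + 1:
        raise ValueError(
            f"{len(shared)} shared genes cannot identify {n_types} "
            "cell types plus an intercept"
        )
    if len(shared) < min_shared_genes:
        warnings.warn(
            f"only {len(shared)} genes shared between bulk and signatures",
            stacklevel=2,
        )
    y = expr.loc[shared].to_numpy(dtype=float)
    x = np.column_stack(
        [np.ones(len(shared)), signatures.loc[shared].to_numpy(dtype=float)]
    )
    cond = float(np.linalg.cond(x))
    if cond > 1e8:
        warnings.warn(
            f"signature matrix is near-collinear (condition number {cond:.3g})",
            stacklevel=2,
        )
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        warnings.warn("rank-deficient signature design", stacklevel=2)
    resid = y - x @ beta
    dof = max(1, len(shared) - x.shape[1])
    samples = expr.columns
    return DeconvolutionResult(
        intercepts=pd.Series(beta[0], index=samples, name="alpha"),
        coefficients=pd.DataFrame(
            beta[1:].T, index=samples, columns=signatures.columns
        ),
        residual_variance=pd.Series(
            (resid**2).sum(axis=0) / dof, index=samples, name="residual_variance"
        ),
        n_shared_genes=len(shared),
        condition_number=cond,
    )


def contribution_age_trend(
    result: DeconvolutionResult, ages: pd.Series | np.ndarray
) -> pd.Series:
    """Spearman rho of each cell type's coefficient with sample age.

    Constant coefficient vectors get rho 0 (flat convention).
    """
    ages = np.asarray(
        ages.reindex(result.coefficients.index) if isinstance(ages, pd.Series) else ages,
        dtype=float,
    )
    if len(ages) < 3:
        raise ValueError("need >= 3 samples")
    coef = result.coefficients.to_numpy(dtype=float).T  # cell type x sample
    rho = spearman_rho_matrix(coef, ages)
    # a spread at rounding-error level is constancy, not a trend
    spread = np.ptp(coef, axis=1)
    scale = np.maximum(1.0, np.abs(coef).max(axis=1))
    rho[spread <= 1e-10 * scale] = 0.0
    return pd.Series(rho, index=result.coefficients.columns, name="rho_vs_age")
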