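"""Trajectory clustering and expression-peak ("turning point") ages.

Per gene and dataset, expression is standardized (mean 0, s.d. 1 within
the dataset), a GCV-smoothed spline of standardized expression against
the fourth root of age in days is fitted, and the spline is evaluated on
a 20-point equally spaced grid spanning the dataset's observed age
range. Concatenating the grids of all datasets gives each gene a
feature vector of 20 x n_datasets values, which k-means partitions into
trajectory clusters. The peak age of a cluster in a dataset is the grid
age (back-converted to years) of the maximum of its mean trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.cluster import KMeans

from .preprocess import AgeSeriesDataset, DAYS_PER_YEAR

logger = logging.getLogger("revaging")

__all__ = [
    "N_GRID",
    "InterpolatedTrajectories",
    "TrajectoryClustering",
    "standardize_and_interpolate",
    "kmeans_trajectories",
    "peak_age",
]

#: Number of interpolation grid points per dataset.
N_GRID = 20


@dataclass
class InterpolatedTrajectories:
    """Spline-interpolated standardized trajectories on per-dataset grids.

    ``values`` is gene x (dataset, grid point) with a two-level column
    index; ``grids`` maps dataset name to its fourth-root-age grid.
    """

    values: pd.DataFrame
    grids: dict[str, np.ndarray]

    @property
    def datasets(self) -> list[str]:
        return list(self.grids)

    def features(self) -> np.ndarray:
        return self.values.to_numpy()

    def grid_years(self, dataset: str) -> np.ndarray:
        return self.grids[dataset] ** 4 / DAYS_PER_YEAR


@dataclass
class TrajectoryClustering:
    k: int
    assignments: pd.Series  # gene -> cluster index
    mean_trajectories: dict[int, pd.DataFrame]  # cluster -> dataset x grid
    peak_ages: pd.DataFrame  # cluster x dataset, years
    inertia: float

    def peak_age_summary(self) -> pd.Series:
        """Cross-dataset median peak age (years) per cluster."""
        return self.peak_ages.median(axis=1)


def _fit_one_spline(x4: np.ndarray, z: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """GCV smoothing spline of standardized expression vs 4th-root age."""
    # aggregate duplicate ages by mean; spline x must be strictly increasing
    order = np.argsort(x4)
    xs, zs = x4[order], z[order]
    ux, inverse = np.unique(xs, return_inverse=True)
    uz = np.bincount(inverse, weights=zs) / np.bincount(inverse)
    spline = make_smoothing_spline(ux, uz)
    return spline(grid)


def standardize_and_interpolate(
    datasets: list[AgeSeriesDataset], genes=None
) -> InterpolatedTrajectories:
    """Standardize per (gene, dataset), fit splines, sample the 20-grid.

    Genes with fewer than 4 distinct ages in any dataset cannot support
    a smoothing spline there and are dropped with a log entry. Constant
    genes standardize to all-zero trajectories.
    """
    if genes is None:
        genes = datasets[0].genes
        for ds in datasets[1:]:
            genes = genes.intersection(ds.genes)
    genes = pd.Index(genes)
    blocks, grids = [], {}
    for ds in datasets:
        x4 = ds.ages_days.to_numpy(dtype=float) ** 0.25
        if len(np.unique(x4)) < 4:
            logger.info("dropping dataset %s: <4 distinct ages", ds.name)
            continue
        grid = np.linspace(x4.min(), x4.max(), N_GRID)
        grids[ds.name] = grid
        expr = ds.expr.loc[genes].to_numpy(dtype=float)
        sd = expr.std(axis=1, ddof=0)
        mean = expr.mean(axis=1)
        block = np.zeros((len(genes), N_GRID))
        for i in range(len(genes)):
            if sd[i] == 0:
                continue  # constant gene: standardized trajectory is 0
            z = (expr[i] - mean[i]) / sd[i]
            block[i] = _fit_one_spline(x4, z, grid)
        cols = pd.MultiIndex.from_product(
            [[ds.name], range(N_GRID)], names=["dataset", "grid"]
        )
        blocks.append(pd.DataFrame(block, index=genes, columns=cols))
    if not blocks:
        raise ValueError("no dataset supports spline interpolation")
    return InterpolatedTrajectories(values=pd.concat(blocks, axis=1), grids=grids)


def kmeans_trajectories(
    trajectories: InterpolatedTrajectories,
    k: int,
    seed: int | None = None,
    n_restarts: int = 10,
) -> TrajectoryClustering:
    """Best-of-restarts k-means over concatenated trajectory features."""
    features = trajectories.features()
    if k > features.shape[0]:
        raise ValueError("k exceeds the number of genes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(features)
    assignments = pd.Series(labels, index=trajectories.values.index, name="cluster")
    mean_trajectories: dict[int, pd.DataFrame] = {}
    peak_rows = {}
    for c in range(k):
        members = trajectories.values[labels == c]
        per_dataset = {}
        peaks = {}
        for name in trajectories.datasets:
            mean_traj = members[name].mean(axis=0).to_numpy()
            per_dataset[name] = mean_traj
            peaks[name] = peak_age(mean_traj, trajectories.grids[name])
        mean_trajectories[c] = pd.DataFrame(per_dataset).T
        peak_rows[c] = peaks
    peak_ages = pd.DataFrame(peak_rows).T
    peak_ages.index.name = "cluster"
    return TrajectoryClustering(
        k=k,
        assignments=assignments,
        mean_trajectories=mean_trajectories,
        peak_ages=peak_ages,
        inertia=float(km.inertia_),
    )


def peak_age(mean_trajectory: np.ndarray, grid: np.ndarray) -> float:
    """Age in years at the trajectory maximum (earliest grid point on ties).

    ``grid`` is on the fourth-root-of-days scale; the returned age is in
    years.
    """
    traj = np.asarray(mean_trajectory, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    idx = int(np.argmax(traj))  # argmax returns the first maximum
    return float(grid[idx] ** 4 / DAYS_PER_YEAR)
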