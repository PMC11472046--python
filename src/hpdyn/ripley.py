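"""Ripley's K / H spatial statistics and localization heatmaps.

K(r) counts, for every ordered point pair closer than the search radius r,
an edge-correction weight, scaled by the inverse point density and the
point count:

    K(r) = lambda^-1 * sum_i sum_{j != i} w_ij * I(r_ij < r) / n

with lambda = n / area.  The nucleus is approximated as a circle; the
isotropic edge correction weights each pair by the inverse of the fraction
of the circle of radius r_ij centred at point i that lies inside the ROI.
H(r) = sqrt(K(r)/pi) - r is 0 under complete spatial randomness, > 0 for
clustering and < 0 for dispersion.  To remove the spatial correlation
between steps of the same trajectory, the data H is compared against
trajectory-matched resampled replicates (same track lengths, ROIs and
density, steps drawn from the empirical step-length distribution):
H_norm = H_data - mean(H_sim).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TrajectorySet, resample_matched_trajectories, subset_by_state

__all__ = [
    "PointPattern",
    "RipleyResult",
    "HeatmapImage",
    "ripley_K",
    "ripley_H",
    "aggregate_cells",
    "normalized_H",
    "render_heatmap",
    "default_r_grid",
]


def default_r_grid() -> np.ndarray:
    """40 search radii from 0.025 to 1.0 um."""
    return np.linspace(0.025, 1.0, 40)


@dataclass
class PointPattern:
    """Planar point pattern inside one circular nucleus ROI."""

    points: np.ndarray  # (n, 2) um
    roi: tuple[float, float, float]  # cx, cy, r (um)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise ValueError("a point pattern needs >= 2 points")
        cx, cy, R = self.roi
        d2 = (self.points[:, 0] - cx) ** 2 + (self.points[:, 1] - cy) ** 2
        if np.any(d2 > R * R * (1 + 1e-9)):
            raise ValueError("all points must lie inside the ROI circle")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        return np.pi * self.roi[2] ** 2

    @property
    def density(self) -> float:
        """Point density lambda = n / area, um^-2."""
        return self.n / self.area


@dataclass
class RipleyResult:
    """Aggregated K/H curves with trajectory-matched normalization."""

    r_grid: np.ndarray
    H: np.ndarray  # data H, aggregated over cells
    H_norm: np.ndarray  # H - mean simulated H
    sim_mean: np.ndarray
    sim_envelope: np.ndarray  # (2, n_r): 2.5% and 97.5% quantiles of sim H
    per_cell: pd.DataFrame  # cell_id, weight, then one column per radius
    K: np.ndarray | None = None
    state: int | None = None


@dataclass
class HeatmapImage:
    """Reconstructed localization density image, globally normalized to 1."""

    image: np.ndarray
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax (um)
    pixel_um: float
    total_intensity: float  # pre-normalization integral (localization count)


def _circle_fraction_inside(d0: np.ndarray, rho: np.ndarray, R: float) -> np.ndarray:
    """Fraction of the circle of radius rho centred at distance d0 from the
    ROI centre that lies inside the ROI circle of radius R."""
    d0 = np.asarray(d0, dtype=float)
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (R * R - d0 * d0 - rho * rho) / (2.0 * d0 * rho)
    c = np.where(d0 * rho == 0, np.where(rho <= R, 1.0, -1.0), c)
    return 1.0 - np.arccos(np.clip(c, -1.0, 1.0)) / np.pi


def ripley_K(
    pattern: PointPattern, r_grid: np.ndarray, edge_correction: bool = True
) -> np.ndarray:
    """Ripley's K over the radius grid (strict inequality r_ij < r).

    Radii exceeding the ROI diameter are computed but flagged unreliable
    via a warning.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    cx, cy, R = pattern.roi
    if np.any(r_grid > 2 * R):
        warnings.warn("some radii exceed the ROI diameter; K there is unreliable", stacklevel=2)
    pts = pattern.points
    n = pattern.n
    d2 = (
        (pts[:, 0, None] - pts[None, :, 0]) ** 2
        + (pts[:, 1, None] - pts[None, :, 1]) ** 2
    )
    np.fill_diagonal(d2, np.inf)
    # only ordered pairs closer than the largest radius can contribute
    ii, jj = np.nonzero(d2 < r_grid.max() ** 2)
    d_ij = np.sqrt(d2[ii, jj])
    if edge_correction:
        d0 = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        frac = _circle_fraction_inside(d0[ii], d_ij, R)
        w = np.where(frac > 0, 1.0 / np.maximum(frac, 1e-12), 0.0)
    else:
        w = np.ones_like(d_ij)
    order = np.argsort(d_ij)
    d_sorted = d_ij[order]
    w_cum = np.concatenate([[0.0], np.cumsum(w[order])])
    idx = np.searchsorted(d_sorted, r_grid, side="left")  # strict: d < r
    return w_cum[idx] / (pattern.density * n)


def ripley_H(K: np.ndarray, r_grid: np.ndarray) -> np.ndarray:
    """H(r) = sqrt(K(r)/pi) - r."""
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("K must be >= 0")
    return np.sqrt(K / np.pi) - np.asarray(r_grid, dtype=float)


def aggregate_cells(H_curves: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Density-weighted mean H over cells (weights normalized to sum 1)."""
    H_curves = np.atleast_2d(np.asarray(H_curves, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must not be all zero")
    w = weights / weights.sum()
    return w @ H_curves


def _aggregate_H_for_set(
    data: TrajectorySet, r_grid: np.ndarray, min_points: int = 2
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-cell H curves aggregated with per-cell fit-density weights."""
    rois = data.rois.set_index("cell_id")
    curves, weights, cells = [], [], []
    for cid, grp in data.df.groupby("cell_id", sort=True):
        if len(grp) < min_points:
            continue
        roi = (rois.loc[cid, "cx_um"], rois.loc[cid, "cy_um"], rois.loc[cid, "r_um"])
        pat = PointPattern(grp[["x_um", "y_um"]].to_numpy(), roi)
        curves.append(ripley_H(ripley_K(pat, r_grid), r_grid))
        weights.append(pat.density)
        cells.append(cid)
    if not curves:
        raise ValueError("no cell has enough points")
    curves = np.asarray(curves)
    weights = np.asarray(weights)
    per_cell = pd.DataFrame(curves, columns=[f"H_r{i}" for i in range(len(r_grid))])
    per_cell.insert(0, "cell_id", cells)
    per_cell.insert(1, "weight", weights / weights.sum())
    return aggregate_cells(curves, weights), per_cell


def normalized_H(
    data: TrajectorySet,
    state: int | None = None,
    labels: np.ndarray | None = None,
    n_reps: int = 100,
    r_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> RipleyResult:
    """Trajectory-matched normalized Ripley H for one mobility state.

    With ``state`` set, the analysis is restricted to maximal runs of steps
    assigned to that state (``labels`` aligned with ``data.steps()``, or
    the ground-truth labels).  ``n_reps`` matched replicates give the
    simulated mean (subtracted from the data H) and the 2.5/97.5% envelope.
    States with fewer than 10 localizations are rejected with a warning.
    """
    if r_grid is None:
        r_grid = default_r_grid()
    subset = data if state is None else subset_by_state(data, state, labels)
    if subset.n_localizations < 10:
        warnings.warn(f"state {state}: fewer than 10 points, skipping", stacklevel=2)
        raise ValueError("too few points for spatial analysis")
    H_data, per_cell = _aggregate_H_for_set(subset, r_grid)
    reps = resample_matched_trajectories(subset, n_reps, seed=seed)
    H_sims = np.asarray([_aggregate_H_for_set(rep, r_grid)[0] for rep in reps])
    sim_mean = H_sims.mean(axis=0)
    envelope = np.percentile(H_sims, [2.5, 97.5], axis=0)
    return RipleyResult(
        r_grid=r_grid,
        H=H_data,
        H_norm=H_data - sim_mean,
        sim_mean=sim_mean,
        sim_envelope=envelope,
        per_cell=per_cell,
        state=state,
    )


def render_heatmap(
    data: TrajectorySet,
    cell_id: int,
    pixel_um: float = 0.02,
    psf_sigma_um: float = 0.04,
) -> HeatmapImage:
    """Reconstructed single-molecule heatmap for one cell.

    Each localization contributes a unit-integral 2-D Gaussian of width
    ``psf_sigma_um`` on a grid of pitch ``pixel_um`` covering the ROI
    (padded by 3 sigma); the image is globally normalized to max 1.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be > 0")
    locs = data.df[data.df["cell_id"] == cell_id]
    if len(locs) == 0:
        raise ValueError(f"no localizations in cell {cell_id}")
    roi = data.rois.set_index("cell_id").loc[cell_id]
    cx, cy, R = roi["cx_um"], roi["cy_um"], roi["r_um"]
    pad = 3 * psf_sigma_um
    xmin, xmax = cx - R - pad, cx + R + pad
    ymin, ymax = cy - R - pad, cy + R + pad
    xg = np.arange(xmin, xmax + pixel_um, pixel_um)
    yg = np.arange(ymin, ymax + pixel_um, pixel_um)
    img = np.zeros((len(yg), len(xg)))
    norm = pixel_um**2 / (2 * np.pi * psf_sigma_um**2)
    for x, y in locs[["x_um", "y_um"]].to_numpy():
        gx = np.exp(-((xg - x) ** 2) / (2 * psf_sigma_um**2))
        gy = np.exp(-((yg - y) ** 2) / (2 * psf_sigma_um**2))
        img += norm * np.outer(gy, gx)
    total = float(img.sum())
    img /= img.max()
    return HeatmapImage(
        image=img,
        extent=(float(xg[0]), float(xg[-1]), float(yg[0]), float(yg[-1])),
        pixel_um=pixel_um,
        total_intensity=total,
    )
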