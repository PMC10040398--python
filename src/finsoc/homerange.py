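"""Kernel utilisation distributions, 95% home ranges, and overlap.

A utilisation distribution (UD) is the probability density of an
animal's space use, estimated here with an isotropic Gaussian kernel on
a regular grid. The 95% isopleth — the smallest set of grid cells
holding 95% of the mass — defines the home range. Pairwise overlap is
the volume of intersection VI = sum over cells of min(f_a, f_b) x cell
area, by default computed after truncating each UD to its own 95% home
range and renormalising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "InsufficientDataError",
    "GridError",
    "UtilisationDistribution",
    "reference_bandwidth",
    "kde_ud",
    "volume_intersection",
    "overlap_matrix",
]

MAX_CELLS_PER_AXIS = 512


class InsufficientDataError(ValueError):
    """Fewer sightings than needed for a kernel density estimate."""


class GridError(ValueError):
    """UDs on incompatible grids that cannot be resampled."""


@dataclass
class UtilisationDistribution:
    """Gridded UD in one or two dimensions.

    ``axes`` holds the grid coordinates per dimension; ``density`` is the
    (renormalised) kernel density on the grid; ``cell_area`` the product
    of grid spacings. Density integrates to 1 within 1e-6.
    """

    axes: tuple[np.ndarray, ...]
    density: np.ndarray
    bandwidth: float

    @property
    def cell_area(self) -> float:
        return float(np.prod([ax[1] - ax[0] for ax in self.axes]))

    def normalise(self) -> None:
        total = self.density.sum() * self.cell_area
        if total <= 0:
            raise ValueError("degenerate UD with zero mass")
        self.density = self.density / total

    def isopleth(self, level: float = 0.95) -> np.ndarray:
        """Smallest boolean cell set containing at least ``level`` mass."""
        flat = self.density.ravel()
        order = np.argsort(flat)[::-1]
        cum = np.cumsum(flat[order]) * self.cell_area
        k = int(np.searchsorted(cum, level) + 1)
        mask = np.zeros(flat.size, dtype=bool)
        mask[order[:k]] = True
        return mask.reshape(self.density.shape)

    def restricted(self, level: float = 0.95) -> "UtilisationDistribution":
        """UD truncated to its ``level`` isopleth and renormalised."""
        dens = np.where(self.isopleth(level), self.density, 0.0)
        ud = UtilisationDistribution(self.axes, dens, self.bandwidth)
        ud.normalise()
        return ud


def reference_bandwidth(points: np.ndarray) -> float:
    """Worton's reference (href) bandwidth for an isotropic kernel.

    h = sigma * n^(-1/6) in two dimensions (sigma the pooled marginal
    standard deviation), h = sigma * n^(-1/5) in one dimension.
    """
    pts = np.atleast_2d(points.astype(float))
    if pts.shape[0] == 1:
        pts = pts.T
    n, d = pts.shape
    sigma = float(np.sqrt(np.mean(np.var(pts, axis=0, ddof=1))))
    exponent = -1.0 / 6.0 if d == 2 else -1.0 / 5.0
    return sigma * n**exponent


def kde_ud(
    points: np.ndarray,
    bandwidth: float | str = "reference",
    cell_size: float | None = None,
    pad_bandwidths: float = 3.0,
    axes: tuple[np.ndarray, ...] | None = None,
) -> UtilisationDistribution:
    """Gaussian-kernel UD on a regular grid.

    The grid extends at least ``pad_bandwidths`` bandwidths beyond the
    data extent with cells of ``bandwidth / 4`` unless ``axes`` provides
    an explicit (shared) grid. Requires at least five sightings.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, d = pts.shape
    if n < 5:
        raise InsufficientDataError(f"need >= 5 points for a UD, got {n}")
    if d not in (1, 2):
        raise ValueError("only 1-D or 2-D UDs are supported")

    if bandwidth == "reference":
        h = reference_bandwidth(pts)
    else:
        h = float(bandwidth)
    if h <= 0:
        h = 1.0  # all points identical: minimal kernel keeps the UD proper

    if axes is None:
        cell = cell_size if cell_size is not None else h / 4.0
        built = []
        for k in range(d):
            lo = pts[:, k].min() - pad_bandwidths * h
            hi = pts[:, k].max() + pad_bandwidths * h
            n_cells = int(np.ceil((hi - lo) / cell)) + 1
            if n_cells > MAX_CELLS_PER_AXIS:
                n_cells = MAX_CELLS_PER_AXIS
            built.append(np.linspace(lo, hi, n_cells))
        axes = tuple(built)

    if d == 1:
        g = np.exp(-0.5 * ((axes[0][None, :] - pts[:, 0:1]) / h) ** 2)
        density = g.sum(axis=0)
    else:
        gx = np.exp(-0.5 * ((axes[0][None, :] - pts[:, 0:1]) / h) ** 2)
        gy = np.exp(-0.5 * ((axes[1][None, :] - pts[:, 1:2]) / h) ** 2)
        density = np.einsum("pi,pj->ij", gx, gy)

    ud = UtilisationDistribution(axes, density, h)
    ud.normalise()
    return ud


def _resample(
    ud: UtilisationDistribution, axes: tuple[np.ndarray, ...]
) -> UtilisationDistribution:
    interp = RegularGridInterpolator(
        ud.axes, ud.density, bounds_error=False, fill_value=0.0
    )
    mesh = np.meshgrid(*axes, indexing="ij")
    dens = interp(np.stack([m.ravel() for m in mesh], axis=-1)).reshape(
        [len(a) for a in axes]
    )
    out = UtilisationDistribution(axes, dens, ud.bandwidth)
    out.normalise()
    return out


def _common_grid(
    a: UtilisationDistribution, b: UtilisationDistribution
) -> tuple[np.ndarray, ...]:
    if len(a.axes) != len(b.axes):
        raise GridError("UDs of different dimensionality")
    axes = []
    for ax_a, ax_b in zip(a.axes, b.axes):
        lo = min(ax_a[0], ax_b[0])
        hi = max(ax_a[-1], ax_b[-1])
        step = min(ax_a[1] - ax_a[0], ax_b[1] - ax_b[0])
        n_cells = int(np.ceil((hi - lo) / step)) + 1
        if n_cells > 4 * MAX_CELLS_PER_AXIS:
            raise GridError("common grid would be unreasonably large")
        axes.append(np.linspace(lo, hi, n_cells))
    return tuple(axes)


def volume_intersection(
    ud_a: UtilisationDistribution,
    ud_b: UtilisationDistribution,
    restrict_95: bool = True,
    level: float = 0.95,
) -> float:
    """Volume of intersection of two UDs, in [0, 1].

    With ``restrict_95`` (the default) each UD is first truncated to its
    own 95% home range and renormalised, matching overlap "of 95% home
    ranges"; otherwise the full UDs are compared.
    """
    if len(ud_a.axes) != len(ud_b.axes):
        raise GridError("UDs of different dimensionality")
    # disjoint extents cannot overlap; skip the common-grid machinery
    for ax_a, ax_b in zip(ud_a.axes, ud_b.axes):
        if ax_a[-1] < ax_b[0] or ax_b[-1] < ax_a[0]:
            return 0.0
    same_grid = all(
        len(x) == len(y) and np.allclose(x, y)
        for x, y in zip(ud_a.axes, ud_b.axes)
    )
    if not same_grid:
        axes = _common_grid(ud_a, ud_b)
        ud_a, ud_b = _resample(ud_a, axes), _resample(ud_b, axes)
    if restrict_95:
        ud_a, ud_b = ud_a.restricted(level), ud_b.restricted(level)
    vi = float(np.minimum(ud_a.density, ud_b.density).sum() * ud_a.cell_area)
    return float(np.clip(vi, 0.0, 1.0))


def overlap_matrix(
    sightings: pd.DataFrame,
    individuals: list[str],
    bandwidth: float | str = "reference",
    restrict_95: bool = True,
    min_points: int = 5,
) -> pd.DataFrame:
    """Pairwise VI matrix from sighting coordinates on one shared grid.

    Individuals with fewer than ``min_points`` sightings receive NaN
    rows (their dyads are masked downstream).
    """
    df = sightings[sightings["individual_id"].isin(individuals)]
    pts_by_ind = {
        ind: sub[["x", "y"]].to_numpy(dtype=float)
        for ind, sub in df.groupby("individual_id")
    }
    # shared grid from the pooled extent; bandwidth per individual (href)
    all_pts = df[["x", "y"]].to_numpy(dtype=float)
    hs = {
        ind: (reference_bandwidth(p) if bandwidth == "reference" else float(bandwidth))
        for ind, p in pts_by_ind.items()
        if len(p) >= min_points
    }
    if not hs:
        raise InsufficientDataError("no individual has enough sightings for a UD")
    h_med = float(np.median(list(hs.values())))
    cell = h_med / 4.0
    axes = []
    for k in range(2):
        lo = all_pts[:, k].min() - 3.0 * h_med
        hi = all_pts[:, k].max() + 3.0 * h_med
        n_cells = min(MAX_CELLS_PER_AXIS, int(np.ceil((hi - lo) / cell)) + 1)
        axes.append(np.linspace(lo, hi, n_cells))
    axes = tuple(axes)

    dens: dict[str, np.ndarray] = {}
    for ind in individuals:
        pts = pts_by_ind.get(ind)
        if pts is None or len(pts) < min_points:
            logger.warning("individual %s has < %d sightings; UD skipped", ind, min_points)
            continue
        ud = kde_ud(pts, bandwidth=hs[ind], axes=axes)
        if restrict_95:
            ud = ud.restricted()
        dens[ind] = ud.density

    cell_area = float((axes[0][1] - axes[0][0]) * (axes[1][1] - axes[1][0]))
    n = len(individuals)
    vi = np.full((n, n), np.nan)
    for i in range(n):
        a = dens.get(individuals[i])
        if a is None:
            continue
        vi[i, i] = 1.0
        for j in range(i + 1, n):
            b = dens.get(individuals[j])
            if b is None:
                continue
            val = np.minimum(a, b).sum() * cell_area
            vi[i, j] = vi[j, i] = min(1.0, max(0.0, float(val)))
    return pd.DataFrame(vi, index=individuals, columns=individuals)
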