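"""Kernel-smoothed occupancy surfaces in PC1 x PC2 niche space.

For each taxon an occurrence density grid ``o`` is estimated on an
R x R lattice spanning the background score range, alongside the
availability density ``e`` of the background itself.  The corrected
occupancy

    r_i = o_i / e_i   where e_i is above the availability floor, else 0
    z   = r / sum(r)

divides out the abundance of climates in the study area, so ``z``
reflects preference rather than climate-space availability.  ``z`` (not
raw ``o``) feeds every overlap statistic downstream.

The smoother is a separable Gaussian-product kernel with per-axis
Silverman reference bandwidths computed on the sample being smoothed;
densities are evaluated at cell centres and treated as discrete masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AvailabilityGrid",
    "NicheDensityGrid",
    "silverman_bandwidth_2d",
    "build_availability_density",
    "build_occupancy",
]

#: default grid resolution per axis
DEFAULT_R = 100

#: default fraction of max(e) below which a cell is outside the
#: availability support (guards the o/e division at the climate fringe)
DEFAULT_AVAILABILITY_FLOOR = 1e-6

#: minimum occupied cells for a meaningful density estimate
MIN_OCCUPIED_CELLS = 5


@dataclass
class AvailabilityGrid:
    """Availability density ``e`` of the background climate space."""

    R: int
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    e: np.ndarray  # (R, R), sums to 1; first axis = PC1 bins
    bandwidth: tuple[float, float]

    @property
    def x_centers(self) -> np.ndarray:
        return _centers(self.x_range, self.R)

    @property
    def y_centers(self) -> np.ndarray:
        return _centers(self.y_range, self.R)

    def support_mask(self, floor: float = DEFAULT_AVAILABILITY_FLOOR) -> np.ndarray:
        return self.e >= floor * self.e.max()


@dataclass
class NicheDensityGrid:
    """One taxon's corrected occupancy surface on the shared availability grid.

    ``o`` is the raw occurrence density, ``e`` the availability density
    (both normalized to sum 1), ``z`` the availability-corrected,
    normalized occupancy; ``z`` is zero wherever ``e`` falls below the
    availability floor.
    """

    R: int
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    n_occ: int
    bandwidth: tuple[float, float]
    availability_floor: float = DEFAULT_AVAILABILITY_FLOOR

    def support_mask(self) -> np.ndarray:
        return self.e >= self.availability_floor * self.e.max()

    def same_frame(self, other: "NicheDensityGrid") -> bool:
        return (
            self.R == other.R
            and np.allclose(self.x_range, other.x_range)
            and np.allclose(self.y_range, other.y_range)
        )


def _centers(rng: tuple[float, float], R: int) -> np.ndarray:
    edges = np.linspace(rng[0], rng[1], R + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def silverman_bandwidth_2d(scores: np.ndarray) -> tuple[float, float]:
    """Per-axis Silverman reference bandwidths for a 2D sample.

    For a bivariate Gaussian reference the rule reduces to
    ``h_k = sigma_k * n^(-1/6)``.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    sd = scores.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise ValueError("degenerate sample: zero variance along a niche axis")
    h = sd * n ** (-1.0 / 6.0)
    return float(h[0]), float(h[1])


def _separable_kde(scores: np.ndarray, xc: np.ndarray, yc: np.ndarray,
                   bandwidth: tuple[float, float]) -> np.ndarray:
    """Gaussian-product KDE evaluated at the grid of (xc x yc) centres.

    Returns an unnormalized (len(xc), len(yc)) mass grid; callers
    normalize to sum 1, so constant factors are dropped.
    """
    hx, hy = bandwidth
    kx = np.exp(-0.5 * ((xc[:, None] - scores[None, :, 0]) / hx) ** 2)
    ky = np.exp(-0.5 * ((yc[:, None] - scores[None, :, 1]) / hy) ** 2)
    return kx @ ky.T


def build_availability_density(background_scores: np.ndarray, R: int = DEFAULT_R,
                               margin: float = 0.05) -> AvailabilityGrid:
    """Estimate the availability density of the background climate space.

    Axis ranges are the background score ranges expanded by ``margin``
    per side so kernel mass near the range limits is not clipped.
    """
    if R < 10:
        raise ValueError(f"grid resolution R={R} too coarse; need R >= 10")
    scores = np.asarray(background_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("background_scores must be (n, 2)")
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 background cells")
    span = scores.max(axis=0) - scores.min(axis=0)
    if np.any(span <= 0):
        raise ValueError("degenerate background: zero score range on an axis")
    lo = scores.min(axis=0) - margin * span
    hi = scores.max(axis=0) + margin * span
    bw = silverman_bandwidth_2d(scores)
    xc, yc = _centers((lo[0], hi[0]), R), _centers((lo[1], hi[1]), R)
    e = _separable_kde(scores, xc, yc, bw)
    e /= e.sum()
    return AvailabilityGrid(R=R, x_range=(float(lo[0]), float(hi[0])),
                            y_range=(float(lo[1]), float(hi[1])), e=e, bandwidth=bw)


def build_occupancy(occ_scores: np.ndarray, availability: AvailabilityGrid,
                    availability_floor: float = DEFAULT_AVAILABILITY_FLOOR,
                    bandwidth: tuple[float, float] | None = None) -> NicheDensityGrid:
    """Build a taxon's availability-corrected occupancy surface.

    ``occ_scores`` are the PC1/PC2 scores of the taxon's occupied climate
    cells (one row per cell, equal weights).  Requires at least
    MIN_OCCUPIED_CELLS rows — the statistic is meaningless for fewer.
    """
    scores = np.asarray(occ_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("occ_scores must be (n, 2)")
    n = scores.shape[0]
    if n < MIN_OCCUPIED_CELLS:
        raise ValueError(
            f"only {n} occupied cells; at least {MIN_OCCUPIED_CELLS} are required — "
            "the occupancy density is meaningless for fewer (skip this taxon)"
        )
    xr, yr = availability.x_range, availability.y_range
    inside = (
        (scores[:, 0] >= xr[0]) & (scores[:, 0] <= xr[1])
        & (scores[:, 1] >= yr[0]) & (scores[:, 1] <= yr[1])
    )
    if not inside.any():
        raise ValueError("all occurrence scores fall outside the niche-grid axis ranges")
    if bandwidth is None:
        bandwidth = silverman_bandwidth_2d(scores)
    o = _separable_kde(scores, availability.x_centers, availability.y_centers, bandwidth)
    o /= o.sum()
    e = availability.e
    support = e >= availability_floor * e.max()
    r = np.zeros_like(o)
    r[support] = o[support] / e[support]
    total = r.sum()
    if total <= 0:
        raise ValueError("occupancy mass vanishes on the availability support")
    z = r / total
    return NicheDensityGrid(
        R=availability.R, x_range=xr, y_range=yr, o=o, e=e, z=z, n_occ=n,
        bandwidth=bandwidth, availability_floor=availability_floor,
    )
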