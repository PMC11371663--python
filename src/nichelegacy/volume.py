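"""Niche volume: how much of the available climate space a taxon occupies.

Two estimators, both relative to the background climate space:

* ``schoener_volume`` — Schoener's D between the taxon's corrected
  occupancy surface and the availability density itself (renormalized
  over the same support); 1 means the taxon fills the available space in
  proportion to its availability.
* ``hdr_volume`` — the fraction of the background's 95% highest-density
  region (HDR) that falls inside the taxon's 95% HDR, both regions taken
  from 2D KDEs on a shared grid.  The HDR is the smallest set of grid
  cells whose summed mass reaches the level, found by sorting cell
  masses in descending order (plateau ties all included).

``compare_volume_groups`` is the report-level comparison between the two
status groups (e.g. regionally extinct vs extant): group medians, a
paired two-tailed t-test on the per-pair differences, and an OLS
regression of one group's volumes on the other's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from nichelegacy.niche_density import (
    DEFAULT_R,
    NicheDensityGrid,
    build_availability_density,
    silverman_bandwidth_2d,
    _separable_kde,
)
from nichelegacy.overlap import schoeners_d

__all__ = [
    "NicheVolume",
    "schoener_volume",
    "hdr_mask",
    "hdr_volume",
    "VolumeComparison",
    "compare_volume_groups",
]

DEFAULT_HDR_LEVEL = 0.95


@dataclass
class NicheVolume:
    taxon: str
    schoener_volume: float
    hdr_volume: float
    hdr_level: float = DEFAULT_HDR_LEVEL


def schoener_volume(grid: NicheDensityGrid) -> float:
    """Schoener's D between a taxon's occupancy ``z`` and the availability ``e``.

    ``e`` is masked to the availability support and renormalized so both
    surfaces are distributions over the same cells; a taxon whose
    occupancy equals the availability scores exactly 1.
    """
    support = grid.support_mask()
    e = np.where(support, grid.e, 0.0)
    e = e / e.sum()
    return schoeners_d(grid.z, e)


def hdr_mask(density: np.ndarray, level: float = DEFAULT_HDR_LEVEL) -> np.ndarray:
    """Highest-density region of a discrete mass grid.

    The smallest set of cells whose summed mass is >= ``level`` times the
    total, obtained by thresholding on cell mass; cells tied at the
    threshold value are all included, so the region is well defined even
    on plateaus.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    d = np.asarray(density, dtype=float)
    flat = np.sort(d.ravel())[::-1]
    csum = np.cumsum(flat)
    target = level * d.sum()
    k = int(np.searchsorted(csum, target))  # first index reaching the level
    threshold = flat[min(k, len(flat) - 1)]
    return d >= threshold


def hdr_volume(taxon_scores: np.ndarray, background_scores: np.ndarray,
               level: float = DEFAULT_HDR_LEVEL, R: int = DEFAULT_R,
               margin: float = 0.05) -> float:
    """Fraction of the background HDR occupied by the taxon HDR.

    Both KDEs are evaluated on the same R x R grid framed by the
    background score range so the two regions are commensurable.
    """
    taxon_scores = np.asarray(taxon_scores, dtype=float)
    if taxon_scores.shape[0] < 5:
        raise ValueError("need at least 5 taxon scores")
    avail = build_availability_density(background_scores, R=R, margin=margin)
    bw_t = silverman_bandwidth_2d(taxon_scores)
    t = _separable_kde(taxon_scores, avail.x_centers, avail.y_centers, bw_t)
    t /= t.sum()
    hdr_bg = hdr_mask(avail.e, level)
    hdr_tx = hdr_mask(t, level)
    return float((hdr_tx & hdr_bg).sum() / hdr_bg.sum())


@dataclass
class VolumeComparison:
    median_extinct: float
    median_extant: float
    t_statistic: float
    p_paired: float
    slope: float
    intercept: float
    r_squared: float
    slope_p: float
    n_pairs: int
    degenerate: bool = False


def compare_volume_groups(extinct: np.ndarray, extant: np.ndarray) -> VolumeComparison:
    """Compare niche volumes between the two status groups of a paired design.

    Returns group medians, the two-tailed paired t-test p on the
    differences, and the OLS fit of extinct on extant volumes.  If every
    within-pair difference is zero the t statistic is undefined; the
    comparison is then reported as p = 1 with a degeneracy flag.
    """
    extinct = np.asarray(extinct, dtype=float)
    extant = np.asarray(extant, dtype=float)
    if extinct.shape != extant.shape:
        raise ValueError("unequal pair lists")
    n = len(extinct)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = extinct - extant
    degenerate = bool(np.all(diffs == 0))
    if degenerate:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(extinct, extant)
    if np.std(extant) == 0:
        slope = intercept = r2 = slope_p = float("nan")
    else:
        fit = stats.linregress(extant, extinct)
        slope, intercept, slope_p = fit.slope, fit.intercept, fit.pvalue
        r2 = fit.rvalue**2
    return VolumeComparison(
        median_extinct=float(np.median(extinct)), median_extant=float(np.median(extant)),
        t_statistic=float(t_stat), p_paired=float(p),
        slope=float(slope), intercept=float(intercept),
        r_squared=float(r2), slope_p=float(slope_p),
        n_pairs=n, degenerate=degenerate,
    )
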