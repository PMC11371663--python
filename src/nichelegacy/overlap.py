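"""Schoener's D overlap and the directional niche randomization tests.

Schoener's D between two normalized occupancy surfaces z1, z2 is

    D = 1 - 1/2 * sum_i |z1_i - z2_i|,

i.e. one minus the total-variation distance between the two discrete
distributions: 0 = disjoint niches, 1 = identical niches.

The similarity test asks whether the observed D is larger than expected
when one taxon's niche is replaced by a niche drawn at random from the
available climate space; the difference test is the opposite tail of the
same null distribution.  Both are directional — each pair is tested
twice, once per taxon randomized — and use the add-one permutation
p-value so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from nichelegacy.niche_density import AvailabilityGrid, NicheDensityGrid, build_occupancy

__all__ = [
    "SimilarityTestResult",
    "schoeners_d",
    "hellinger_affinity",
    "similarity_test",
    "adjust_pvalues",
    "classify_pair",
    "dagger",
]

_NORM_TOL = 1e-6

#: Table-2-style footnote symbols for the directional categories
_DAGGERS = {
    "similar_both": "‡", "different_both": "‡",
    "similar_one": "†", "different_one": "†",
    "non_similar": "–", "not_different": "–",
}

ADJUST_METHODS = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh", "none": None}


def _check_pair(z1: np.ndarray, z2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError(f"occupancy grids differ in shape: {z1.shape} vs {z2.shape}")
    for name, z in (("z1", z1), ("z2", z2)):
        if abs(z.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"{name} is not normalized (sum = {z.sum():.8f})")
    return z1, z2


def schoeners_d(z1: np.ndarray, z2: np.ndarray) -> float:
    """Schoener's D between two normalized occupancy surfaces, in [0, 1]."""
    z1, z2 = _check_pair(z1, z2)
    d = 1.0 - 0.5 * np.abs(z1 - z2).sum()
    return float(min(1.0, max(0.0, d)))


def hellinger_affinity(z1: np.ndarray, z2: np.ndarray) -> float:
    """Warren's I (Hellinger-based affinity), an optional cross-check metric."""
    z1, z2 = _check_pair(z1, z2)
    h2 = 0.5 * ((np.sqrt(z1) - np.sqrt(z2)) ** 2).sum()
    return float(min(1.0, max(0.0, 1.0 - h2)))


@dataclass
class SimilarityTestResult:
    """Directional similarity/difference test for one ordered taxon pair."""

    randomized: str              # label of the taxon whose niche was randomized
    fixed: str                   # label of the taxon held at its observed niche
    d_obs: float
    null_d: np.ndarray           # B replicate D values
    p_similarity: float          # P(null D >= observed D), add-one estimator
    p_difference: float          # P(null D <= observed D), add-one estimator
    B: int
    seed: int
    strategy: str

    def __post_init__(self) -> None:
        assert len(self.null_d) == self.B


def _translate(z: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Shift a mass grid by whole cells, clipping at the edges (no wrap)."""
    out = np.zeros_like(z)
    R, C = z.shape
    if abs(di) >= R or abs(dj) >= C:
        return out
    out[max(0, di):R + min(0, di), max(0, dj):C + min(0, dj)] = \
        z[max(0, -di):R + min(0, -di), max(0, -dj):C + min(0, -dj)]
    return out


def _mass_centroid_cell(z: np.ndarray) -> tuple[int, int]:
    R, C = z.shape
    i = int(round(float((z.sum(axis=1) * np.arange(R)).sum())))
    j = int(round(float((z.sum(axis=0) * np.arange(C)).sum())))
    return i, j


def similarity_test(
    grid_ran: NicheDensityGrid,
    grid_fix: NicheDensityGrid,
    B: int = 1000,
    seed: int = 0,
    strategy: str = "shift",
    background_scores: np.ndarray | None = None,
    randomized: str = "a",
    fixed: str = "b",
) -> SimilarityTestResult:
    """Directional niche similarity/difference randomization test.

    ``grid_ran`` is the taxon whose niche is randomized within the
    available climate space; ``grid_fix`` keeps its observed surface.
    Two null strategies are available:

    ``"shift"`` (default)
        relocate the observed occupancy surface to a centroid drawn
        uniformly from the availability-support cells (translate, clip to
        the grid, zero outside the support, renormalize).  Preserves the
        observed niche shape, testing placement only.
    ``"resample"``
        redraw ``n_occ`` occupied cells uniformly from the background
        (requires ``background_scores``) and rebuild the occupancy
        surface; replaces shape and placement together.

    p_similarity = (1 + #{null D >= D_obs}) / (B + 1) tests for niches
    more similar than random; p_difference uses the opposite tail.
    """
    if B < 99:
        raise ValueError("B must be at least 99 for a meaningful permutation p-value")
    if not grid_ran.same_frame(grid_fix):
        raise ValueError("niche grids do not share axes/resolution")
    support = grid_ran.support_mask()
    sup_idx = np.argwhere(support)
    if len(sup_idx) == 0:
        raise ValueError("availability support is empty")
    rng = np.random.default_rng(seed)
    d_obs = schoeners_d(grid_ran.z, grid_fix.z)
    null_d = np.empty(B)

    if strategy == "shift":
        ci, cj = _mass_centroid_cell(grid_ran.z)
        targets = sup_idx[rng.integers(0, len(sup_idx), size=B)]
        for b in range(B):
            di, dj = int(targets[b, 0]) - ci, int(targets[b, 1]) - cj
            znull = _translate(grid_ran.z, di, dj)
            znull[~support] = 0.0
            total = znull.sum()
            # a surface shifted entirely off the support has no overlap to offer
            null_d[b] = 0.0 if total <= 0 else schoeners_d(znull / total, grid_fix.z)
    elif strategy == "resample":
        if background_scores is None:
            raise ValueError("strategy 'resample' requires background_scores")
        bg = np.asarray(background_scores, dtype=float)
        n = grid_ran.n_occ
        avail = AvailabilityGrid(
            R=grid_ran.R, x_range=grid_ran.x_range, y_range=grid_ran.y_range,
            e=grid_ran.e, bandwidth=(np.nan, np.nan),
        )
        replace = n > len(bg)
        for b in range(B):
            idx = rng.choice(len(bg), size=n, replace=replace)
            znull = build_occupancy(bg[idx], avail,
                                    availability_floor=grid_ran.availability_floor).z
            null_d[b] = schoeners_d(znull, grid_fix.z)
    else:
        raise ValueError(f"unknown null strategy {strategy!r}")

    p_sim = (1.0 + (null_d >= d_obs).sum()) / (B + 1.0)
    p_dif = (1.0 + (null_d <= d_obs).sum()) / (B + 1.0)
    return SimilarityTestResult(
        randomized=randomized, fixed=fixed, d_obs=d_obs, null_d=null_d,
        p_similarity=float(p_sim), p_difference=float(p_dif),
        B=B, seed=seed, strategy=strategy,
    )


def adjust_pvalues(pvalues, method: str = "holm") -> np.ndarray:
    """Multiple-comparison adjustment; adjusted p are monotone and >= raw."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}; "
                         f"choose from {sorted(ADJUST_METHODS)}")
    if ADJUST_METHODS[method] is None or len(p) == 0:
        return p.copy()
    _, adj, _, _ = multipletests(p, method=ADJUST_METHODS[method])
    return np.maximum(adj, p)


def classify_pair(p_sim: tuple[float, float], p_diff: tuple[float, float],
                  alpha: float = 0.05) -> tuple[str, str]:
    """Classify a pair from its two directional adjusted p-values.

    Similarity: both directions significant -> ``similar_both``, one ->
    ``similar_one``, none -> ``non_similar``; analogously for the
    difference test.  A pair that is neither similar nor different in any
    direction is the candidate "climate legacy" pattern.
    """
    n_sim = sum(p < alpha for p in p_sim)
    n_dif = sum(p < alpha for p in p_diff)
    sim = {2: "similar_both", 1: "similar_one", 0: "non_similar"}[n_sim]
    dif = {2: "different_both", 1: "different_one", 0: "not_different"}[n_dif]
    return sim, dif


def dagger(category: str) -> str:
    """Footnote symbol for a directional category (double dagger / dagger / dash)."""
    return _DAGGERS[category]
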