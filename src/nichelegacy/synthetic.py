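"""Synthetic climate landscapes and occurrence sets with known niche structure.

The generator emulates the shape of the real inputs — inter-correlated
bioclim-style variables on a lon/lat lattice, an availability mask, and
GBIF-style occurrence tables — while keeping the underlying niches known
exactly, so every downstream stage can be tested without downloads.

Climate model: each cell carries L latent spatial factors (an east-west
gradient, a north-south gradient, and optionally a smoothed random
field), standardized over the lattice.  The V observed variables are
fixed unit-norm linear mixtures of the latents plus independent Gaussian
noise, giving a climate table whose correlation structure has exactly L
dominant axes — the two-axis "temperature vs seasonality/precipitation"
structure of real bioclim PCAs.  The background mask keeps the central
quantile band of latent factor 1 (default central 70%), mimicking the
exclusion of an arid interior without any climate classification.

Occurrences: a species' niche is a Gaussian in latent-factor space;
records pick background cells with probability proportional to the
Gaussian density at the cell's latent value, are jittered uniformly
within the cell, and receive log-normal coordinate uncertainties with a
configurable missing fraction (to exercise the filter's missing-value
policy).  All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from nichelegacy.grids import ClimateGrid, write_ascii_grid

__all__ = [
    "LandscapeSpec",
    "NicheSpec",
    "Landscape",
    "PairScenario",
    "generate_climate_landscape",
    "sample_occurrences",
    "make_pair_scenario",
    "write_landscape",
    "write_occurrences_csv",
]

PRESETS = ("identical", "shifted", "nested")


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic climate landscape."""

    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 0.05          # degrees per cell
    n_vars: int = 19                 # bioclim-style variable count
    latent_dim: int = 2
    mixing: np.ndarray | None = None  # (n_vars, latent_dim); default: unit-norm seeded rows
    noise_sd: float = 0.1            # independent per-variable noise, latent-SD units
    background_band: tuple[float, float] = (0.15, 0.85)  # quantile band on factor 1
    west: float = 140.0
    north: float = -20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("n_rows and n_cols must be at least 4")
        if not (1 <= self.latent_dim <= self.n_vars):
            raise ValueError("need n_vars >= latent_dim >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class NicheSpec:
    """A Gaussian niche in latent climate-factor space."""

    centroid: np.ndarray             # (latent_dim,)
    breadth: np.ndarray | float      # scalar, per-factor SDs, or full covariance
    n_records: int = 200
    uncertainty_median_m: float = 500.0
    uncertainty_log_sd: float = 1.0
    missing_uncertainty_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.centroid = np.atleast_1d(np.asarray(self.centroid, dtype=float))
        if self.n_records < 1:
            raise ValueError("n_records must be at least 1")
        b = np.asarray(self.breadth, dtype=float)
        if b.ndim < 2 and np.any(b <= 0):
            raise ValueError("breadth entries must be positive")

    def covariance(self) -> np.ndarray:
        b = np.asarray(self.breadth, dtype=float)
        k = len(self.centroid)
        if b.ndim == 0:
            return np.eye(k) * float(b) ** 2
        if b.ndim == 1:
            return np.diag(b**2)
        return b


@dataclass
class Landscape:
    """A generated climate grid, its availability mask, and the latent truth."""

    grid: ClimateGrid
    mask: np.ndarray                 # (n_rows, n_cols) bool availability mask
    latent: np.ndarray               # (n_rows, n_cols, latent_dim) standardized factors
    mixing: np.ndarray               # (n_vars, latent_dim) realized loading matrix
    spec: LandscapeSpec


def _latent_fields(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = np.mgrid[0:spec.n_rows, 0:spec.n_cols].astype(float)
    fields = [cols, -rows]  # east-west gradient; north-south (north = high)
    while len(fields) < spec.latent_dim:
        # low-frequency random field: heavy Gaussian smoothing of white noise
        raw = rng.standard_normal((spec.n_rows, spec.n_cols))
        fields.append(ndimage.gaussian_filter(raw, sigma=min(spec.n_rows, spec.n_cols) / 6))
    out = np.empty((spec.n_rows, spec.n_cols, spec.latent_dim))
    for k in range(spec.latent_dim):
        f = fields[k]
        out[:, :, k] = (f - f.mean()) / f.std()
    return out


def _default_mixing(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    # unit-norm rows: every variable has unit signal variance, so noise_sd
    # directly sets the noise-to-signal ratio
    g = rng.standard_normal((spec.n_vars, spec.latent_dim))
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    return g / norms


def generate_climate_landscape(spec: LandscapeSpec) -> Landscape:
    """Generate a climate grid plus availability mask; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    latent = _latent_fields(spec, rng)
    mixing = spec.mixing
    if mixing is None:
        mixing = _default_mixing(spec, rng)
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape != (spec.n_vars, spec.latent_dim):
        raise ValueError(f"mixing must be ({spec.n_vars}, {spec.latent_dim})")
    if not np.any(mixing):
        raise ValueError("degenerate mixing matrix (all zeros)")
    signal = latent @ mixing.T  # (rows, cols, n_vars)
    noise = spec.noise_sd * rng.standard_normal(signal.shape)
    # arbitrary per-variable affine units so centring/scaling downstream is exercised
    offsets = 10.0 * np.arange(1, spec.n_vars + 1)
    scales = 1.0 + (np.arange(spec.n_vars) % 5)
    values = offsets + scales * (signal + noise)
    grid = ClimateGrid(
        west=spec.west, north=spec.north, cell_size=spec.cell_size,
        values=values, var_names=[f"bio{i + 1}" for i in range(spec.n_vars)],
    )
    f1 = latent[:, :, 0]
    lo, hi = np.quantile(f1, spec.background_band)
    mask = (f1 >= lo) & (f1 <= hi)
    return Landscape(grid=grid, mask=mask, latent=latent, mixing=mixing, spec=spec)


#: record-basis mix emulating a herbarium-dominated GBIF download
_BASIS_CHOICES = np.array(["PRESERVED_SPECIMEN", "HUMAN_OBSERVATION", "LIVING_SPECIMEN"])
_BASIS_PROBS = np.array([0.6, 0.35, 0.05])


def sample_occurrences(landscape: Landscape, niche: NicheSpec,
                       taxon: str = "Genus") -> pd.DataFrame:
    """Draw a GBIF-style occurrence table from a Gaussian niche.

    Cells are drawn from the background with probability proportional to
    the niche density at the cell's latent-factor value; coordinates are
    jittered uniformly within the drawn cell.  Returns a DataFrame with
    Darwin-Core-style columns.
    """
    rng = np.random.default_rng(niche.seed)
    rows, cols = np.nonzero(landscape.mask & landscape.grid.valid_mask())
    if len(rows) == 0:
        raise ValueError("landscape has no background cells")
    x = landscape.latent[rows, cols, :]  # (n_bg, L)
    k = x.shape[1]
    mu = niche.centroid
    if len(mu) != k:
        raise ValueError(f"centroid has {len(mu)} entries; landscape has {k} latent factors")
    cov = niche.covariance()
    prec = np.linalg.inv(cov)
    dx = x - mu
    log_w = -0.5 * np.einsum("ij,jk,ik->i", dx, prec, dx)
    # deliberately unshifted: a centroid far outside the landscape underflows
    # every weight to zero and must error, not silently return an empty set
    w = np.exp(log_w)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all selection probabilities are zero: niche centroid "
                         "lies far outside the landscape's climate range")
    p = w / total
    draws = rng.choice(len(rows), size=niche.n_records, p=p)
    cs = landscape.grid.cell_size
    lon = landscape.grid.west + (cols[draws] + rng.uniform(0, 1, niche.n_records)) * cs
    lat = landscape.grid.north - (rows[draws] + rng.uniform(0, 1, niche.n_records)) * cs
    unc = np.exp(np.log(niche.uncertainty_median_m)
                 + niche.uncertainty_log_sd * rng.standard_normal(niche.n_records))
    missing = rng.uniform(0, 1, niche.n_records) < niche.missing_uncertainty_frac
    unc = np.where(missing, np.nan, unc)
    basis = rng.choice(_BASIS_CHOICES, size=niche.n_records, p=_BASIS_PROBS)
    return pd.DataFrame({
        "genus": taxon,
        "species": [f"{taxon} sp."] * niche.n_records,
        "decimalLongitude": lon,
        "decimalLatitude": lat,
        "coordinateUncertaintyInMeters": unc,
        "basisOfRecord": basis,
    })


@dataclass
class PairScenario:
    landscape: Landscape
    occurrences_a: pd.DataFrame      # the "extinct-in-region" taxon
    occurrences_b: pd.DataFrame      # the "extant-in-region" taxon
    niche_a: NicheSpec
    niche_b: NicheSpec
    preset: str


def make_pair_scenario(preset: str, separation: float = 2.0, n_per_species: int = 500,
                       seed: int = 0, breadth: float = 0.5, nested_ratio: float = 2.0,
                       landscape: Landscape | None = None,
                       landscape_spec: LandscapeSpec | None = None,
                       taxa: tuple[str, str] = ("GenusA", "GenusB")) -> PairScenario:
    """Build a two-species test scenario with a known niche relationship.

    ``identical`` — both species share one niche (only the record seeds
    differ); ``shifted`` — centroids separated by ``separation`` along
    latent factor 2 (the full-range north-south axis); ``nested`` — same
    centroid, the second species ``nested_ratio`` times broader.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if landscape is None:
        if landscape_spec is None:
            landscape_spec = LandscapeSpec(seed=seed)
        landscape = generate_climate_landscape(landscape_spec)
    k = landscape.latent.shape[2]
    base = np.zeros(k)
    ca, cb = base.copy(), base.copy()
    ba = bb = breadth
    if preset == "shifted":
        axis = 1 if k > 1 else 0
        ca[axis] -= separation / 2
        cb[axis] += separation / 2
    elif preset == "nested":
        bb = breadth * nested_ratio
    niche_a = NicheSpec(centroid=ca, breadth=ba, n_records=n_per_species, seed=seed * 2 + 1)
    niche_b = NicheSpec(centroid=cb, breadth=bb, n_records=n_per_species, seed=seed * 2 + 2)
    occ_a = sample_occurrences(landscape, niche_a, taxon=taxa[0])
    occ_b = sample_occurrences(landscape, niche_b, taxon=taxa[1])
    return PairScenario(landscape=landscape, occurrences_a=occ_a, occurrences_b=occ_b,
                        niche_a=niche_a, niche_b=niche_b, preset=preset)


def write_landscape(landscape: Landscape, out_dir: str | Path) -> dict[str, Path]:
    """Write one ESRI ASCII raster per variable plus the availability mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = landscape.grid
    paths: dict[str, Path] = {}
    for i, name in enumerate(g.var_names):
        path = out_dir / f"{name}.asc"
        write_ascii_grid(path, g.values[:, :, i], g.west, g.north, g.cell_size)
        paths[name] = path
    mask_path = out_dir / "background_mask.asc"
    write_ascii_grid(mask_path, landscape.mask.astype(float), g.west, g.north, g.cell_size)
    paths["background_mask"] = mask_path
    return paths


def write_occurrences_csv(occ: pd.DataFrame, path: str | Path) -> None:
    occ.to_csv(path, index=False)
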