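"""Environmental PCA over the available (background) climate space.

The niche space is built by the "PCA-env" convention: the PCA is
calibrated on the background cells only — every valid cell inside the
availability mask, each weighted once — and occurrences are projected
into that space afterwards.  Variables are centred and scaled to unit
variance over the background (correlation-matrix PCA), which makes
degrees Celsius and millimetres commensurable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from nichelegacy.grids import ClimateGrid, GridGeometryError

__all__ = [
    "BackgroundSet",
    "EnvironmentalSpace",
    "apply_background_mask",
    "fit_environmental_pca",
    "project",
]

log = logging.getLogger(__name__)


@dataclass
class BackgroundSet:
    """Valid climate cells inside the availability mask.

    ``rows``/``cols`` index the parent grid; ``X`` is the (n, V) matrix of
    per-cell climate vectors, ``var_names`` its column names.
    """

    rows: np.ndarray
    cols: np.ndarray
    X: np.ndarray
    var_names: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise ValueError("background set is empty")
        if self.X.shape != (len(self.rows), len(self.var_names)):
            raise ValueError("X shape inconsistent with indices / variable names")

    @property
    def n_cells(self) -> int:
        return len(self.rows)


@dataclass
class EnvironmentalSpace:
    """A fitted environmental PCA: centring, scaling, loadings, variance.

    ``loadings`` is (V, K) with orthonormal columns; ``var_fraction``
    sums to one over all K retained components.  ``score_range`` stores
    the background score min/max per axis for the first two components,
    used downstream to frame the niche grid.
    """

    var_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    var_fraction: np.ndarray
    score_range: np.ndarray  # (2, 2): [[min1, max1], [min2, max2]]
    dropped: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "var_names": self.var_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "var_fraction": self.var_fraction.tolist(),
            "score_range": self.score_range.tolist(),
            "dropped": self.dropped,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnvironmentalSpace":
        obj = json.loads(Path(path).read_text())
        return cls(
            var_names=obj["var_names"],
            center=np.asarray(obj["center"]),
            scale=np.asarray(obj["scale"]),
            loadings=np.asarray(obj["loadings"]),
            var_fraction=np.asarray(obj["var_fraction"]),
            score_range=np.asarray(obj["score_range"]),
            dropped=list(obj.get("dropped", [])),
        )


def apply_background_mask(grid: ClimateGrid, mask: np.ndarray) -> BackgroundSet:
    """Restrict a climate grid to the available climate space.

    ``mask`` is a boolean (n_rows, n_cols) array (e.g. a Koppen-style
    climate-zone raster thresholded upstream).  The background is the set
    of cells that are both valid (no missing variable) and inside the
    mask.
    """
    mask = np.asarray(mask)
    if mask.shape != (grid.n_rows, grid.n_cols):
        raise GridGeometryError(
            f"mask shape {mask.shape} does not match grid ({grid.n_rows}, {grid.n_cols})"
        )
    keep = grid.valid_mask() & mask.astype(bool)
    rows, cols = np.nonzero(keep)
    if len(rows) == 0:
        raise ValueError("background is empty after masking")
    X = grid.values[rows, cols, :]
    log.info("background: %d of %d cells retained", len(rows), grid.n_rows * grid.n_cols)
    return BackgroundSet(rows=rows, cols=cols, X=X, var_names=list(grid.var_names))


def fit_environmental_pca(background: BackgroundSet, n_axes: int = 2,
                          require_components: int = 2) -> EnvironmentalSpace:
    """Fit the correlation-matrix PCA on background cells.

    Each background cell is weighted equally.  Zero-variance variables
    are dropped with a warning.  Components are ordered by decreasing
    variance and each component's sign is flipped so its largest-magnitude
    loading is positive (a deterministic convention; SVD signs are
    otherwise arbitrary).  A niche space needs two informative axes, so
    fewer than ``require_components`` informative components is an error;
    pass ``require_components=1`` to fit a deliberately rank-deficient
    table (e.g. to inspect its variance fractions).
    """
    X = np.asarray(background.X, dtype=float)
    names = list(background.var_names)
    n = X.shape[0]
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    keep = scale > 0
    dropped = [nm for nm, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance variables after masking: {dropped}")
        log.warning("dropping zero-variance variables: %s", dropped)
        X, center, scale = X[:, keep], center[keep], scale[keep]
        names = [nm for nm, k in zip(names, keep) if k]
    V = X.shape[1]
    if n < V + 1:
        raise ValueError(f"need at least {V + 1} background cells for a {V}-variable PCA, got {n}")
    Z = (X - center) / scale
    # thin SVD of the standardized table; eigvals of the correlation matrix = s^2/(n-1)
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    informative = int((eigvals > total * 1e-12).sum())
    if informative < require_components:
        raise ValueError(
            f"only {informative} informative principal component(s); "
            f"{require_components} required"
        )
    loadings = Vt.T  # (V, K), orthonormal columns
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    var_fraction = eigvals / total
    scores = Z @ loadings[:, :n_axes]
    score_range = np.stack([scores.min(axis=0), scores.max(axis=0)], axis=1)
    return EnvironmentalSpace(
        var_names=names,
        center=center,
        scale=scale,
        loadings=loadings,
        var_fraction=var_fraction,
        score_range=score_range,
        dropped=dropped,
    )


def project(space: EnvironmentalSpace, X: np.ndarray, var_names: list[str] | None = None,
            n_axes: int = 2) -> np.ndarray:
    """Project climate vectors into the fitted space.

    ``X`` is (n, V) with columns in ``space.var_names`` order, or in the
    order given by ``var_names`` (missing variables raise).  Returns
    (n, n_axes) scores; the background mean maps to the origin.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if var_names is not None:
        missing = [v for v in space.var_names if v not in var_names]
        if missing:
            raise KeyError(f"input lacks required variables: {missing}")
        order = [var_names.index(v) for v in space.var_names]
        X = X[:, order]
    if X.shape[1] != len(space.var_names):
        raise ValueError(
            f"expected {len(space.var_names)} variables, got {X.shape[1]}"
        )
    Z = (X - space.center) / space.scale
    return Z @ space.loadings[:, :n_axes]
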