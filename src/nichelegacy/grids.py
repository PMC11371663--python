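"""Gridded climate layers and plain-text raster I/O.

A :class:`ClimateGrid` is a regular lon/lat lattice carrying V named
climate variables per cell (bio1..bio19 semantics: temperatures in
degrees C, precipitation in mm, seasonality indices unitless).  Rasters
are read and written as ESRI ASCII grids, one variable per file; all
layers of one grid must share an identical geometry — a mismatch is an
error, never a silent resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ClimateGrid",
    "GridGeometryError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_climate_grid",
]

#: default sentinel used when writing rasters
NODATA = -9999.0

#: relative tolerance for comparing raster geometries
_GEOM_RTOL = 1e-9


class GridGeometryError(ValueError):
    """Raster layers do not share a common geometry."""


@dataclass
class ClimateGrid:
    """Lattice of cells carrying V climate variables plus a nodata mask.

    Parameters
    ----------
    west, north
        Coordinates of the grid's north-west corner, in degrees.
    cell_size
        Cell edge length in degrees (cells are square in degrees).
    values
        Array of shape ``(n_rows, n_cols, V)``; missing values are NaN.
        Row 0 is the northernmost row (raster convention).
    var_names
        Names of the V variables, e.g. ``["bio1", ..., "bio19"]``.
    """

    west: float
    north: float
    cell_size: float
    values: np.ndarray
    var_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_rows, n_cols, n_vars)")
        if not self.var_names:
            self.var_names = [f"var{i + 1}" for i in range(self.values.shape[2])]
        if len(self.var_names) != self.values.shape[2]:
            raise ValueError("var_names length does not match values depth")
        if len(set(self.var_names)) != len(self.var_names):
            raise ValueError("duplicate variable name")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_vars(self) -> int:
        return self.values.shape[2]

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    def valid_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols): a cell is valid only if *all* variables are present."""
        return np.isfinite(self.values).all(axis=2)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a coordinate to its (row, col) cell, or ``None`` if outside the grid.

        Membership follows a half-open convention so every point belongs to
        exactly one cell: lon in [west_edge, east_edge), lat in
        (south_edge, north_edge].
        """
        if not (self.west <= lon < self.east):
            return None
        if not (self.south < lat <= self.north):
            return None
        col = int(np.floor((lon - self.west) / self.cell_size))
        row = int(np.floor((self.north - lat) / self.cell_size))
        col = min(col, self.n_cols - 1)
        row = min(row, self.n_rows - 1)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.west + (col + 0.5) * self.cell_size
        lat = self.north - (row + 0.5) * self.cell_size
        return lon, lat


def write_ascii_grid(path: str | Path, layer: np.ndarray, west: float, north: float,
                     cell_size: float, nodata: float = NODATA) -> None:
    """Write one 2D layer (row 0 = north) as an ESRI ASCII grid."""
    layer = np.asarray(layer, dtype=float)
    n_rows, n_cols = layer.shape
    out = np.where(np.isfinite(layer), layer, nodata)
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {west!r}\n"
        f"yllcorner {north - n_rows * cell_size!r}\n"
        f"cellsize {cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid; returns (layer, west, north, cell_size).

    Nodata cells come back as NaN.  Both ``xllcorner`` and ``xllcenter``
    header dialects are accepted.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key!r}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} does not match header")
    cs = header["cellsize"]
    if "xllcorner" in header:
        west = header["xllcorner"]
    elif "xllcenter" in header:
        west = header["xllcenter"] - cs / 2
    else:
        raise ValueError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        north = header["yllcorner"] + n_rows * cs
    elif "yllcenter" in header:
        north = header["yllcenter"] - cs / 2 + n_rows * cs
    else:
        raise ValueError(f"{path}: missing yllcorner/yllcenter")
    if "nodata_value" in header:
        data = np.where(data == header["nodata_value"], np.nan, data)
    return data, west, north, cs


def read_climate_grid(paths: dict[str, str | Path]) -> ClimateGrid:
    """Assemble a :class:`ClimateGrid` from one raster file per variable.

    Parameters
    ----------
    paths
        Mapping of variable name -> raster path.  All rasters must share
        the same geometry; a mismatch raises :class:`GridGeometryError`.
    """
    if not paths:
        raise ValueError("no raster paths given")
    names = list(paths)
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable name")
    layers = []
    geom = None
    for name in names:
        layer, west, north, cs = read_ascii_grid(paths[name])
        this = (layer.shape, west, north, cs)
        if geom is None:
            geom = this
        else:
            same = (
                this[0] == geom[0]
                and np.isclose(this[1], geom[1], rtol=_GEOM_RTOL, atol=1e-9)
                and np.isclose(this[2], geom[2], rtol=_GEOM_RTOL, atol=1e-9)
                and np.isclose(this[3], geom[3], rtol=_GEOM_RTOL, atol=1e-9)
            )
            if not same:
                raise GridGeometryError(
                    f"raster {paths[name]} geometry {this[1:]} (shape {this[0]}) "
                    f"differs from first layer {geom[1:]} (shape {geom[0]})"
                )
        layers.append(layer)
    values = np.stack(layers, axis=2)
    return ClimateGrid(west=geom[1], north=geom[2], cell_size=geom[3],
                       values=values, var_names=names)
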