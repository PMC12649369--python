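"""Georeferenced cell lattices and value surfaces.

A :class:`GridDef` describes a regular longitude/latitude lattice anchored at
its north-west corner; a :class:`Raster` is a 2-D value surface on such a
lattice.  All map-valued quantities in the package (climate predictors,
elevation, cold-stress counts, suitability, binary habitat masks) are
Rasters.  Cells are half-open: a point on the northern/western edge of a
cell belongs to it, a point on the southern/eastern edge belongs to the
next cell, except on the outer grid boundary where points are clamped so
the grid covers its extent totally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: 30 arc-seconds in degrees, the working resolution (~1 km at the equator).
DEFAULT_CELL_SIZE = 1.0 / 120.0


@dataclass(frozen=True)
class GridDef:
    """Regular lon/lat lattice defined by its north-west corner.

    Parameters
    ----------
    west_lon, north_lat:
        Coordinates of the outer north-west corner, in degrees.
    cell_size:
        Cell edge length in degrees (default 30 arc-seconds).
    n_rows, n_cols:
        Lattice dimensions; row 0 is the northernmost row.
    nodata:
        Sentinel used for missing cells in rasters on this grid.
    """

    west_lon: float
    north_lat: float
    n_rows: int
    n_cols: int
    cell_size: float = DEFAULT_CELL_SIZE
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not (-180.0 <= self.west_lon <= 180.0):
            raise ValueError(f"west_lon {self.west_lon} outside [-180, 180]")
        if not (-90.0 <= self.south_lat and self.north_lat <= 90.0):
            raise ValueError("grid extends outside valid latitudes")

    @property
    def east_lon(self) -> float:
        return self.west_lon + self.n_cols * self.cell_size

    @property
    def south_lat(self) -> float:
        return self.north_lat - self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, lon, lat) -> np.ndarray:
        """Vectorised extent test (outer boundary inclusive)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.west_lon)
            & (lon <= self.east_lon)
            & (lat >= self.south_lat)
            & (lat <= self.north_lat)
        )

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col).

        Half-open cells; points exactly on the southern/eastern outer
        boundary are clamped into the last row/column so every point in the
        extent maps to exactly one cell.  Points outside the extent raise.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        if not np.all(inside):
            bad = np.nonzero(~np.atleast_1d(inside))[0]
            raise ValueError(
                f"{bad.size} point(s) outside grid extent (indices {bad[:10].tolist()})"
            )
        row = np.floor((self.north_lat - lat) / self.cell_size).astype(int)
        col = np.floor((lon - self.west_lon) / self.cell_size).astype(int)
        row = np.clip(row, 0, self.n_rows - 1)
        col = np.clip(col, 0, self.n_cols - 1)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.west_lon + (col + 0.5) * self.cell_size
        lat = self.north_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def row_center_lats(self) -> np.ndarray:
        """Cell-center latitude of every row, north to south."""
        rows = np.arange(self.n_rows)
        return self.north_lat - (rows + 0.5) * self.cell_size


@dataclass
class Raster:
    """A named value surface on a :class:`GridDef`.

    ``values`` is float; missing cells hold ``grid.nodata`` (NaN is also
    treated as missing on input and normalised to the sentinel).
    """

    grid: GridDef
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        self.values = np.where(np.isnan(self.values), self.grid.nodata, self.values)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.grid.nodata

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_equal(self.values, self.grid.nodata)

    def sample(self, lon, lat) -> np.ndarray:
        """Value at the cell containing each point (nodata propagates)."""
        row, col = self.grid.cell_index(lon, lat)
        return self.values[row, col]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Raster":
        return Raster(self.grid, values, self.name if name is None else name)


def check_same_grid(*rasters: Raster) -> GridDef:
    grids = {r.grid for r in rasters}
    if len(grids) != 1:
        raise ValueError("rasters are not on a common grid")
    return rasters[0].grid


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, corner-registered)."""
    g = raster.grid
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.west_lon:.10g}\n"
        f"yllcorner {g.south_lat:.10g}\n"
        f"cellsize {g.cell_size:.12g}\n"
        f"NODATA_value {g.nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.8g")


def read_ascii_grid(path: str | Path, name: str = "") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    grid = GridDef(
        west_lon=header["xllcorner"],
        north_lat=header["yllcorner"] + n_rows * cell,
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        nodata=header.get("nodata_value", -9999.0),
    )
    return Raster(grid, values.reshape(n_rows, n_cols), name or Path(path).stem)
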