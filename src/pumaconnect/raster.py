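"""Lightweight georeferenced raster grid.

A :class:`RasterGrid` is a single-band 2-D float array with square cells,
an affine anchor (lower-left corner + cell size, north-up) and a nodata
sentinel. Row 0 is the northernmost row, matching the on-disk layout of
the ESRI ASCII grid format used for text I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class RasterGrid:
    """Single-band raster with affine georeferencing.

    Parameters
    ----------
    values : ndarray
        2-D float array, row 0 = top (north).
    xll, yll : float
        Coordinates of the lower-left corner of the grid, in the
        projected CRS (meters).
    cell_size : float
        Square cell edge length in meters.
    crs : str
        Opaque CRS tag (the package never reprojects).
    nodata : float
        Sentinel for invalid cells.
    """

    values: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cell_size: float = 270.0
    crs: str = "local-meters"
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        v = self.values
        return np.isfinite(v) & (v != self.nodata)

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """(x, y) coordinates of cell centers for array indices."""
        x = self.xll + (np.asarray(col) + 0.5) * self.cell_size
        y = self.yll + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def index_of(self, x, y):
        """Array indices (row, col) of the cells containing points."""
        col = np.floor((np.asarray(x) - self.xll) / self.cell_size).astype(int)
        row = (self.n_rows - 1
               - np.floor((np.asarray(y) - self.yll) / self.cell_size).astype(int))
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.index_of(x, y)
        return ((row >= 0) & (row < self.n_rows)
                & (col >= 0) & (col < self.n_cols))

    def center_grids(self):
        """Meshgrid of x and y center coordinates, shaped like values."""
        rows, cols = np.mgrid[0:self.n_rows, 0:self.n_cols]
        return self.cell_center(rows, cols)

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeferencing."""
        return RasterGrid(values, self.xll, self.yll, self.cell_size,
                          self.crs, self.nodata)

    def same_grid(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.xll, other.xll)
                and np.isclose(self.yll, other.yll)
                and np.isclose(self.cell_size, other.cell_size))

    # -- text I/O (ESRI ASCII grid) ------------------------------------
    def write_ascii(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.xll}\n")
            fh.write(f"yllcorner {self.yll}\n")
            fh.write(f"cellsize {self.cell_size}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            out = np.where(self.mask, self.values, self.nodata)
            np.savetxt(fh, out, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path, crs: str = "local-meters") -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            pos = fh.tell()
            for _ in range(6):
                line = fh.readline()
                key, val = line.split()
                header[key.lower()] = float(val)
                pos = fh.tell()
            fh.seek(pos)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        nodata = header.get("nodata_value", NODATA)
        values = np.where(values == nodata, nodata, values)
        return cls(values, header["xllcorner"], header["yllcorner"],
                   header["cellsize"], crs, nodata)
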