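"""Raster grid geometry and plain-text (ESRI ASCII) raster I/O.

All spatial work in this package happens in a local metric CRS (metres), so a
grid is fully described by its lower-left origin, square cell size and shape.
Rasters are stored row-major with row 0 at the TOP of the extent (image
convention), matching the ESRI ASCII grid layout used for on-disk exchange.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class RasterGrid:
    """Geometry shared by every layer of a covariate stack or surface."""

    x0: float  # lower-left corner x (m)
    y0: float  # lower-left corner y (m)
    cell: float  # square cell size (m)
    nrows: int
    ncols: int

    @property
    def width(self) -> float:
        return self.ncols * self.cell

    @property
    def height(self) -> float:
        return self.nrows * self.cell

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of shape (nrows, ncols), row 0 on top."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cells containing points (clipped to the grid)."""
        col = np.clip(((np.asarray(x) - self.x0) / self.cell).astype(int), 0, self.ncols - 1)
        row_from_bottom = np.clip(((np.asarray(y) - self.y0) / self.cell).astype(int), 0, self.nrows - 1)
        return self.nrows - 1 - row_from_bottom, col

    def aggregate(self, factor: int) -> "RasterGrid":
        if factor < 1:
            raise ValueError("aggregation factor must be >= 1")
        return RasterGrid(
            self.x0, self.y0, self.cell * factor,
            self.nrows // factor, self.ncols // factor,
        )


def block_aggregate(layer: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean aggregation by an integer factor (trailing remainder dropped).

    NaN cells are ignored within each block; an all-NaN block stays NaN.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    if factor == 1:
        return layer.copy()
    nr = (layer.shape[0] // factor) * factor
    nc = (layer.shape[1] // factor) * factor
    trimmed = layer[:nr, :nc]
    blocks = trimmed.reshape(nr // factor, factor, nc // factor, factor)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks, axis=(1, 3))


def write_ascii_grid(path: str | Path, grid: RasterGrid, layer: np.ndarray) -> None:
    """Write one layer as an ESRI ASCII grid (row 0 = top row)."""
    arr = np.where(np.isfinite(layer), layer, NODATA)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0}\n"
        f"cellsize {grid.cell}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[RasterGrid, np.ndarray]:
    with open(path) as fh:
        meta = {}
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = meta.get("nodata_value", NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    grid = RasterGrid(
        meta["xllcorner"], meta["yllcorner"], meta["cellsize"],
        int(meta["nrows"]), int(meta["ncols"]),
    )
    return grid, arr
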