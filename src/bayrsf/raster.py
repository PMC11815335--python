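"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Grids are stored row-major with row 0 at the *top* (largest y), matching the
ASCII-grid convention, on a square-cell, axis-aligned grid in the working
projected CRS (metres).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid"]


@dataclass
class Raster:
    values: np.ndarray      # (nrows, ncols), row 0 = top
    x0: float               # x of the *left edge* of the grid
    y0: float               # y of the *bottom edge* of the grid
    cell: float             # cell size, metres
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, same shape as values."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrows)[::-1] + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) indices for point coordinates."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = self.nrows - 1 - np.floor((y - self.y0) / self.cell).astype(int)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell sampling; off-grid points return NaN."""
        row, col = self.rowcol(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        out = np.full(row.shape, np.nan)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out[ok] = self.values[row[ok], col[ok]]
        out[out == self.nodata] = np.nan
        return out if out.size > 1 else out.reshape(())

    def aligned_with(self, other: "Raster", tol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x0 - other.x0) < tol
            and abs(self.y0 - other.y0) < tol
            and abs(self.cell - other.cell) < tol
        )

    def write_ascii_grid(self, path: str | Path) -> None:
        vals = np.where(np.isnan(self.values), self.nodata, self.values)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0!r}\n"
            f"cellsize {self.cell!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> Raster:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = hdr.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return Raster(
        values=values,
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"],
        cell=hdr["cellsize"],
        nodata=nodata,
    )
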