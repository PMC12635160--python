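"""Planar raster grid container with Esri ASCII grid serialization.

All analysis rasters (elevation relative to mean higher high water,
gridded population) live on north-up, square-cell grids in a planar
metric CRS. The Esri ASCII grid format is used on disk: it is plain
text, self-describing (origin, cell size, nodata), and round-trips the
float32 payloads used here without loss at the stored precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster: ``values[row, col]`` with row 0 at the north edge.

    Parameters
    ----------
    values
        2-D float array; ``NODATA`` marks missing cells.
    xmin, ymin
        Coordinates of the lower-left corner of the grid extent (m).
    cell
        Cell edge length (m).
    """

    values: np.ndarray
    xmin: float
    ymin: float
    cell: float
    crs: str = "synthetic-planar-meters"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cell

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, shape (nrows, ncols)."""
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.ymax - (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing the point; raises if outside."""
        col = int(np.floor((x - self.xmin) / self.cell))
        row = int(np.floor((self.ymax - y) / self.cell))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.index_of(x, y)
        return float(self.values[r, c])

    def mask_valid(self) -> np.ndarray:
        return self.values != NODATA

    # ---- I/O -------------------------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        path = Path(path)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xmin!r}\n"
            f"yllcorner {self.ymin!r}\n"
            f"cellsize {self.cell!r}\n"
            f"NODATA_value {NODATA!r}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.6f")

    @classmethod
    def read_ascii(cls, path: str | Path, crs: str = "synthetic-planar-meters") -> "Grid":
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(
            values=values,
            xmin=meta["xllcorner"],
            ymin=meta["yllcorner"],
            cell=meta["cellsize"],
            crs=crs,
        )
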