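"""Georeferenced single-band raster grids on a planar metric coordinate system.

``RasterGrid`` is the universal currency of the pipeline: the DEM, every
bioclimatic layer, climate axes, suitability maps, binary projections and
velocity surfaces are all instances of it.  Coordinates are projected metres
(planar Euclidean distances), cells are square, row 0 is the northern edge and
cell (0, 0) is the top-left cell.  A point (x, y) belongs to the half-open cell
``[x0 + j*s, x0 + (j+1)*s) x (y0 - (i+1)*s, y0 - i*s]``.

Missing data is represented as NaN in the float array.  I/O uses the ESRI
ASCII grid format, a plain-text raster interchange format readable by every
GIS stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when an operation requires congruent grids and gets different ones."""


@dataclass
class RasterGrid:
    """A single-band raster: 2-D float array plus a square-cell geotransform.

    Parameters
    ----------
    data:
        2-D float array; NaN marks nodata cells.
    cell_m:
        Cell side length in metres.
    x0, y0:
        Coordinates of the grid's top-left CORNER (west edge of column 0,
        north edge of row 0), in projected metres.
    """

    data: np.ndarray
    cell_m: float
    x0: float = 0.0
    y0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if self.cell_m <= 0:
            raise ValueError("cell size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, each of grid shape."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        x = self.x0 + (cols + 0.5) * self.cell_m
        y = self.y0 - (rows + 0.5) * self.cell_m
        return x, y

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (half-open cell rule)."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.cell_m).astype(int)
        row = np.floor((self.y0 - np.asarray(y, float)) / self.cell_m).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.cell_index(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def congruent(self, other: "RasterGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_m - other.cell_m) <= atol
            and abs(self.x0 - other.x0) <= atol
            and abs(self.y0 - other.y0) <= atol
        )

    def require_congruent(self, other: "RasterGrid", what: str = "rasters") -> None:
        if not self.congruent(other):
            raise GridMismatchError(
                f"{what} are not congruent: {self.shape}@{self.cell_m} m vs "
                f"{other.shape}@{other.cell_m} m"
            )

    # -- derivation ---------------------------------------------------------
    def like(self, data: np.ndarray) -> "RasterGrid":
        """A new grid sharing this one's geotransform."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise ValueError(f"shape {data.shape} does not match grid {self.shape}")
        return RasterGrid(data, self.cell_m, self.x0, self.y0, dict(self.meta))

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.data.copy(), self.cell_m, self.x0, self.y0, dict(self.meta))

    def block_aggregate(self, factor: int, how: str = "mean") -> "RasterGrid":
        """Aggregate ``factor`` x ``factor`` blocks of cells into one coarse cell.

        NaNs are ignored within a block; an all-NaN block stays NaN.
        """
        if factor < 1 or self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"grid {self.shape} not divisible into {factor}x{factor} blocks"
            )
        blocks = self.data.reshape(
            self.n_rows // factor, factor, self.n_cols // factor, factor
        ).swapaxes(1, 2)
        flat = blocks.reshape(blocks.shape[0], blocks.shape[1], -1)
        with np.errstate(invalid="ignore"):
            if how == "mean":
                agg = np.nanmean(flat, axis=2)
            elif how == "sum":
                agg = np.nansum(flat, axis=2)
                agg[np.all(np.isnan(flat), axis=2)] = np.nan
            else:
                raise ValueError(f"unknown aggregation {how!r}")
        return RasterGrid(agg, self.cell_m * factor, self.x0, self.y0)

    # -- I/O (ESRI ASCII grid) ---------------------------------------------
    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        path = Path(path)
        data = np.where(np.isnan(self.data), nodata, self.data)
        yll = self.y0 - self.n_rows * self.cell_m
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.cell_m!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = header.get("nodata_value", -9999.0)
        data[data == nodata] = np.nan
        cell = header["cellsize"]
        nrows = int(header["nrows"])
        y0 = header["yllcorner"] + nrows * cell
        return cls(data, cell, header["xllcorner"], y0)
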