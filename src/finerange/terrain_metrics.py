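"""Terrain derivatives: slope/aspect (Horn), northness/eastness, irradiation
proxy, terrain ruggedness (TRI), topographic complexity (TCI), and nearest-
neighbour resampling between resolutions.

Conventions
-----------
Slope is in radians, ``atan`` of the Horn 8-neighbour gradient magnitude.
Aspect is the azimuth of the *upslope* (gradient) direction, clockwise from
north, in [0, 2*pi); a plane rising eastward has aspect pi/2.  Flat cells get
aspect 0 by convention and are flagged in ``TerrainStack.flat``.  The one-cell
raster border, where the 3x3 stencil is incomplete, is nodata for slope and
aspect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid

__all__ = [
    "TerrainStack",
    "HeterogeneityIndices",
    "resample_nearest",
    "slope_aspect",
    "northness_eastness",
    "dni_proxy",
    "tri",
    "tci",
    "build_terrain_stack",
]


@dataclass
class TerrainStack:
    """The five topographic predictors used for statistical downscaling."""

    elevation: RasterGrid
    slope: RasterGrid
    aspect: RasterGrid
    northness: RasterGrid
    eastness: RasterGrid
    dni: RasterGrid
    flat: np.ndarray | None = None  # True where aspect was undefined

    def predictor_matrix(self) -> np.ndarray:
        """(n_cells, 5) matrix: elevation, slope, northness, eastness, dni."""
        return np.column_stack(
            [
                g.data.ravel()
                for g in (self.elevation, self.slope, self.northness, self.eastness, self.dni)
            ]
        )

    PREDICTOR_NAMES = ("elevation", "slope", "northness", "eastness", "dni")


@dataclass
class HeterogeneityIndices:
    tri: RasterGrid
    tci: RasterGrid


def resample_nearest(dem: RasterGrid, target_cell_m: float) -> RasterGrid:
    """Nearest-neighbour resampling to a coarser or finer square grid.

    The target grid shares the source's top-left corner; each output cell
    takes the value of the source cell containing its center.
    """
    ratio = target_cell_m / dem.cell_m
    inv = dem.cell_m / target_cell_m
    if not (
        abs(ratio - round(ratio)) < 1e-9 and ratio >= 1
    ) and not (abs(inv - round(inv)) < 1e-9 and inv >= 1):
        raise ValueError(
            f"target cell {target_cell_m} m is neither a multiple nor a divisor "
            f"of source cell {dem.cell_m} m"
        )
    n_rows = int(round(dem.n_rows * dem.cell_m / target_cell_m))
    n_cols = int(round(dem.n_cols * dem.cell_m / target_cell_m))
    if n_rows == 0 or n_cols == 0:
        raise ValueError("target grid would be empty")
    rows = np.clip(((np.arange(n_rows) + 0.5) * ratio).astype(int), 0, dem.n_rows - 1)
    cols = np.clip(((np.arange(n_cols) + 0.5) * ratio).astype(int), 0, dem.n_cols - 1)
    return RasterGrid(dem.data[np.ix_(rows, cols)], target_cell_m, dem.x0, dem.y0)


def _horn_gradient(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Horn's 8-neighbour finite differences dz/dx (east+) and dz/dy (north+).

    Returns full-shape arrays with NaN on the one-cell border.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("slope/aspect need at least a 3x3 raster")
    z = dem.data
    s = dem.cell_m
    gx = np.full(dem.shape, np.nan)
    gy = np.full(dem.shape, np.nan)
    # stencil letters:  a b c   (row-1)
    #                   d e f
    #                   g h i   (row+1)
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx[1:-1, 1:-1] = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * s)
    # row index grows southward, so northward derivative uses (top - bottom)
    gy[1:-1, 1:-1] = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * s)
    return gx, gy


def slope_aspect(dem: RasterGrid, flat_tol: float = 1e-12) -> tuple[RasterGrid, RasterGrid]:
    """Slope (radians) and upslope aspect (radians clockwise from north).

    Flat cells (gradient magnitude below ``flat_tol``) get aspect 0.  The
    flat-cell mask is stored in ``aspect.meta['flat']``.
    """
    gx, gy = _horn_gradient(dem)
    mag = np.hypot(gx, gy)
    slope = np.arctan(mag)
    aspect = np.mod(np.arctan2(gx, gy), 2 * np.pi)
    flat = mag <= flat_tol
    aspect[flat & ~np.isnan(mag)] = 0.0
    s = dem.like(slope)
    a = dem.like(aspect)
    a.meta["flat"] = flat & ~np.isnan(mag)
    return s, a


def northness_eastness(aspect: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """cos(aspect) and sin(aspect); NaN propagates."""
    return aspect.like(np.cos(aspect.data)), aspect.like(np.sin(aspect.data))


def dni_proxy(
    slope: RasterGrid, aspect: RasterGrid, latitude_deg: float, dni_flat: float = 1500.0
) -> RasterGrid:
    """Clear-sky direct-irradiation proxy (kWh/m^2), from noon sun geometry.

    Incidence on a tilted surface with the sun due south at elevation
    (90 deg - latitude): ``cos(theta) = cos(s)*sin(h) + sin(s)*cos(h)*cos(aspect)``
    where, with the upslope-aspect convention, cos(aspect) = 1 identifies a
    south-facing (downslope-south) cell in the northern hemisphere.  Clipped
    away from zero so the proxy stays strictly positive on self-shaded cells.
    """
    slope.require_congruent(aspect, "slope and aspect")
    h = np.deg2rad(90.0 - latitude_deg)
    cos_theta = np.cos(slope.data) * np.sin(h) + np.sin(slope.data) * np.cos(h) * np.cos(
        aspect.data
    )
    val = dni_flat / np.sin(h) * np.clip(cos_theta, 0.02, None)
    return slope.like(val)


_NEIGHBOR_SHIFTS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def tri(dem: RasterGrid) -> RasterGrid:
    """Terrain ruggedness index: mean |center - neighbour| over the
    8-neighbourhood; border cells average over their existing neighbours."""
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("TRI needs at least a 3x3 raster")
    z = np.pad(dem.data, 1, constant_values=np.nan)
    diffs = np.stack(
        [
            np.abs(dem.data - z[1 + di : 1 + di + dem.n_rows, 1 + dj : 1 + dj + dem.n_cols])
            for di, dj in _NEIGHBOR_SHIFTS
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighbourhoods
        out = np.nanmean(diffs, axis=0)
    return dem.like(out)


def tci(dem_fine: RasterGrid, coarse_cell_m: float) -> RasterGrid:
    """Topographic complexity index: 3D / 2D surface-area ratio per coarse cell.

    Each fine cell contributes a slope-corrected area ``A_fine / cos(slope)``;
    the ratio of the summed 3D area to the planimetric coarse-cell area equals
    the mean of ``1/cos(slope)`` over the fine cells, computed here with
    NaN-aware averaging so the one-cell slope border and near-vertical cells
    (excluded with a warning) do not bias the ratio.  TCI >= 1, with equality
    on perfectly flat terrain.
    """
    factor = coarse_cell_m / dem_fine.cell_m
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("fine cell size must divide the coarse cell size")
    factor = int(round(factor))
    slope, _ = slope_aspect(dem_fine)
    ratio = 1.0 / np.cos(slope.data)
    vertical = slope.data >= np.pi / 2 - 1e-9
    if vertical.any():
        warnings.warn(f"{vertical.sum()} near-vertical cell(s) excluded from TCI")
        ratio[vertical] = np.nan
    grid = dem_fine.like(ratio)
    if factor == 1:
        return grid
    # trim rows/cols if the fine grid does not tile exactly
    nr = (dem_fine.n_rows // factor) * factor
    nc = (dem_fine.n_cols // factor) * factor
    trimmed = RasterGrid(ratio[:nr, :nc], dem_fine.cell_m, dem_fine.x0, dem_fine.y0)
    return trimmed.block_aggregate(factor, how="mean")


def build_terrain_stack(
    dem_fine: RasterGrid, latitude_deg: float = 46.0
) -> TerrainStack:
    """All five downscaling predictors from a fine-resolution DEM."""
    slope, aspect = slope_aspect(dem_fine)
    north, east = northness_eastness(aspect)
    dni = dni_proxy(slope, aspect, latitude_deg)
    return TerrainStack(
        elevation=dem_fine,
        slope=slope,
        aspect=aspect,
        northness=north,
        eastness=east,
        dni=dni,
        flat=aspect.meta.get("flat"),
    )
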