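"""Multivariate climate-change velocity by nearest-analog search.

The two climate axes are discretized into 120 unique-climate bins (a 12 x 10
grid over the pooled baseline+future axis ranges).  For each cell the minimum
planar distance to any cell whose *future* climate falls in the same bin as
the cell's *baseline* climate is divided by the number of years between the
climate periods; the published scale is CCV = 100 * log10(velocity in m/yr).
Zero distances are floored at half a cell width before the log so the scale
stays finite; cells whose baseline climate has no future analog anywhere are
flagged rather than given a number.  Per-GCM CCV surfaces are averaged on the
log (CCV) scale to give one surface per emission scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .grid import RasterGrid

__all__ = [
    "ClimateBinning",
    "VelocitySurface",
    "bin_climate",
    "classify_with_binning",
    "nearest_analog_distance",
    "ccv_transform",
    "average_over_gcms",
]

DEFAULT_BIN_SHAPE = (12, 10)  # 120 unique-climate classes


@dataclass
class ClimateBinning:
    """Equal-width 2-D binning of the (PC1, PC2) plane."""

    edges1: np.ndarray  # len n1+1
    edges2: np.ndarray  # len n2+1
    shape: tuple[int, int]

    @property
    def n_bins(self) -> int:
        return self.shape[0] * self.shape[1]

    def classify(self, pc1: RasterGrid, pc2: RasterGrid) -> RasterGrid:
        """Integer class raster (flattened bin index); NaN where axes are NaN."""
        pc1.require_congruent(pc2, "climate axes")
        i = np.clip(np.digitize(pc1.data, self.edges1) - 1, 0, self.shape[0] - 1)
        j = np.clip(np.digitize(pc2.data, self.edges2) - 1, 0, self.shape[1] - 1)
        cls = (i * self.shape[1] + j).astype(float)
        cls[np.isnan(pc1.data) | np.isnan(pc2.data)] = np.nan
        return pc1.like(cls)


@dataclass
class VelocitySurface:
    distance_m: RasterGrid
    velocity_m_per_yr: RasterGrid
    ccv: RasterGrid  # 100 * log10(m / yr)
    delta_years: float
    no_analog: np.ndarray  # bool mask
    meta: dict = field(default_factory=dict)


def _axis_edges(vals: list[np.ndarray], n: int) -> np.ndarray:
    lo = min(np.nanmin(v) for v in vals)
    hi = max(np.nanmax(v) for v in vals)
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("degenerate climate axis (all NaN)")
    if hi <= lo:
        warnings.warn("degenerate axis range; using a single bin on that axis")
        hi = lo + 1.0
        n = 1
    edges = np.linspace(lo, hi, n + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max
    return edges


def bin_climate(
    axes_baseline: tuple[RasterGrid, RasterGrid],
    axes_future: list[tuple[RasterGrid, RasterGrid]] | tuple[RasterGrid, RasterGrid],
    bin_shape: tuple[int, int] = DEFAULT_BIN_SHAPE,
) -> ClimateBinning:
    """Bin edges spanning the pooled (baseline and future) axis ranges."""
    if isinstance(axes_future, tuple) and isinstance(axes_future[0], RasterGrid):
        axes_future = [axes_future]
    all1 = [axes_baseline[0].data] + [a[0].data for a in axes_future]
    all2 = [axes_baseline[1].data] + [a[1].data for a in axes_future]
    n1, n2 = bin_shape
    if n1 < 1 or n2 < 1:
        raise ValueError("bin shape must be positive")
    e1 = _axis_edges(all1, n1)
    e2 = _axis_edges(all2, n2)
    # a degenerate axis collapses to a single bin on that axis
    return ClimateBinning(e1, e2, (len(e1) - 1, len(e2) - 1))


def classify_with_binning(
    binning: ClimateBinning, pc1: RasterGrid, pc2: RasterGrid
) -> RasterGrid:
    return binning.classify(pc1, pc2)


def nearest_analog_distance(
    class_baseline: RasterGrid, class_future: RasterGrid
) -> tuple[RasterGrid, np.ndarray]:
    """Per-cell minimum distance (m) to a future cell of the same climate class.

    Distances are cell-center to cell-center; a cell whose own future class
    matches its baseline class gets 0.  Returns (distance raster, no-analog
    mask); no-analog cells are NaN in the raster.
    """
    class_baseline.require_congruent(class_future, "class rasters")
    if class_baseline.data.size == 0:
        raise ValueError("empty class rasters")
    b = class_baseline.data
    f = class_future.data
    x, y = class_baseline.cell_centers()
    dist = np.full(b.shape, np.nan)
    no_analog = np.zeros(b.shape, dtype=bool)
    valid_b = ~np.isnan(b)
    future_classes = f[~np.isnan(f)]
    for c in np.unique(b[valid_b]):
        sel = valid_b & (b == c)
        targets = (f == c) & ~np.isnan(f)
        if not targets.any():
            no_analog |= sel
            continue
        tree = cKDTree(np.column_stack([x[targets], y[targets]]))
        d, _ = tree.query(np.column_stack([x[sel], y[sel]]), k=1)
        dist[sel] = d
    no_analog &= valid_b
    return class_baseline.like(dist), no_analog


def ccv_transform(
    distance_m: RasterGrid, delta_years: float, floor_m: float | None = None
) -> tuple[RasterGrid, RasterGrid]:
    """(velocity m/yr, CCV = 100*log10(velocity)) from analog distances.

    ``floor_m`` (default: half a cell width) bounds distances away from zero
    so the log scale stays finite for self-analog cells.
    """
    if delta_years <= 0:
        raise ValueError("delta_years must be positive")
    if floor_m is None:
        floor_m = distance_m.cell_m / 2.0
    vel = np.maximum(distance_m.data, floor_m) / delta_years
    vel[np.isnan(distance_m.data)] = np.nan
    with np.errstate(invalid="ignore"):
        ccv = 100.0 * np.log10(vel)
    velocity = distance_m.like(vel)
    out = distance_m.like(ccv)
    out.meta["floor_m"] = floor_m
    out.meta["delta_years"] = delta_years
    return velocity, out


def average_over_gcms(
    ccv_per_gcm: list[RasterGrid],
    no_analog_per_gcm: list[np.ndarray] | None = None,
    delta_years: float = 74.0,
) -> VelocitySurface:
    """Cell-wise mean CCV over GCMs, ignoring per-GCM no-analog cells.

    A cell is flagged no-analog in the result only when every GCM lacked an
    analog there.  Distance and velocity are back-transformed from the mean
    CCV (i.e. geometric-mean velocity), matching averaging on the log scale.
    """
    if not ccv_per_gcm:
        raise ValueError("need at least one GCM surface")
    first = ccv_per_gcm[0]
    for g in ccv_per_gcm[1:]:
        first.require_congruent(g, "CCV surfaces")
    stack = np.stack([g.data for g in ccv_per_gcm])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN stacks
        mean_ccv = np.nanmean(stack, axis=0)
    if no_analog_per_gcm is not None:
        all_missing = np.logical_and.reduce(no_analog_per_gcm)
    else:
        all_missing = np.isnan(stack).all(axis=0)
    mean_ccv[all_missing] = np.nan
    vel = np.power(10.0, mean_ccv / 100.0)
    return VelocitySurface(
        distance_m=first.like(vel * delta_years),
        velocity_m_per_yr=first.like(vel),
        ccv=first.like(mean_ccv),
        delta_years=delta_years,
        no_analog=all_missing,
    )
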