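"""Synthetic mountain landscape with known ground truth.

Generates every input the range-dynamics pipeline consumes: a DEM whose
hypsometry mimics dolomitic massifs (flat valley floors, steep mid-elevation
slopes, high flat plateaus), 19 mutually correlated bioclimatic layers driven
by elevation, per-GCM perturbed and per-rcp warmed future climates, a
spatially autocorrelated binary carbonate-geology mask, and virtual-species
occurrences sampled from a known Gaussian climatic niche.

Every generator is a pure function of (config, seed): rerunning with the same
arguments is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import RasterGrid
from .scenarios import ClimateScenario, N_BIOCLIM, TEMP_WEIGHTS

__all__ = [
    "LandscapeConfig",
    "SpeciesTruth",
    "make_dem",
    "make_bioclim",
    "make_geology_mask",
    "true_suitability",
    "make_species",
    "thin_occurrences",
]


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    The fine grid (cell ``fine_cell_m``, default 50 m) carries terrain and all
    downscaled products; the coarse grid (``coarse_factor`` fine cells per
    side, default 20, i.e. ~1 km climate on a 50 m terrain grid) carries the
    raw bioclimatic layers.
    """

    extent_cells: tuple[int, int] = (160, 160)
    fine_cell_m: float = 50.0
    coarse_factor: int = 20
    plateau_elevation_m: float = 3000.0
    valley_elevation_m: float = 1000.0
    lapse_rate_K_per_km: float = 6.5
    rcp_offsets_K: dict[str, float] = field(
        default_factory=lambda: {"rcp45": 2.2, "rcp85": 4.3}
    )
    n_gcm: int = 5
    gcm_jitter_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        nr, nc = self.extent_cells
        if nr <= 0 or nc <= 0:
            raise ValueError("extent_cells must be positive")
        if nr % self.coarse_factor or nc % self.coarse_factor:
            raise ValueError(
                f"extent {self.extent_cells} not divisible by coarse_factor {self.coarse_factor}"
            )
        if self.plateau_elevation_m <= self.valley_elevation_m:
            raise ValueError("plateau elevation must exceed valley elevation")
        if not self.rcp_offsets_K:
            raise ValueError("at least one rcp offset is required")

    @property
    def gcm_tags(self) -> list[str]:
        return [f"gcm{i + 1}" for i in range(self.n_gcm)]


@dataclass
class SpeciesTruth:
    """Ground-truth climatic niche of a virtual species.

    ``niche_center``/``niche_breadth`` live in the (PC1, PC2) climate-axis
    space; ``prevalence`` is the fraction of the landscape truly suitable and
    is used when deriving a binary "true range" from the suitability surface.
    """

    species_id: str
    niche_center: tuple[float, float]
    niche_breadth: tuple[float, float]
    n_occurrences: int = 150
    prevalence: float = 0.25

    def __post_init__(self) -> None:
        if self.n_occurrences <= 30:
            raise ValueError(
                "species need more than 30 occurrences to be modelled; "
                f"{self.species_id!r} has {self.n_occurrences}"
            )
        if min(self.niche_breadth) <= 0:
            raise ValueError("niche breadth must be strictly positive")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field with correlation length sigma."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_dem(config: LandscapeConfig) -> RasterGrid:
    """Fine-grid DEM with flat valleys, steep mid-slopes and high plateaus.

    A long-wavelength random field is squashed through a logistic ramp between
    the valley and plateau elevations: the extremes of the field map onto the
    flats, its mid-range onto the steep flanks, so the slope distribution
    peaks at middle elevations.  Low-amplitude multi-octave noise roughens the
    surface without destroying that structure.
    """
    rng = np.random.default_rng([config.seed, 0])
    shape = config.extent_cells
    base = _smooth_field(rng, shape, sigma=min(shape) / 6)
    # rank-normalize so terrain fractions are stable across seeds
    order = base.ravel().argsort().argsort()
    u = (order + 0.5) / order.size
    u = u.reshape(shape)
    relief = config.plateau_elevation_m - config.valley_elevation_m
    # summit plateaus of different massifs differ in height (up to a quarter
    # of the relief), so the coldest climates are not a single flat level
    summit = _smooth_field(rng, shape, sigma=min(shape) / 4)
    summit = (summit - summit.min()) / (summit.max() - summit.min() + 1e-12)
    relief_local = relief * (1.0 - 0.25 * summit)
    ramp = 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5)))
    elev = config.valley_elevation_m + relief_local * ramp
    # fractal roughness: three octaves, ~1% of total relief
    noise = sum(
        _smooth_field(rng, shape, sigma) * amp
        for sigma, amp in ((8, 0.6), (3, 0.3), (1, 0.1))
    )
    elev = elev + noise * 0.01 * relief
    elev = np.clip(elev, config.valley_elevation_m, config.plateau_elevation_m)
    return RasterGrid(elev, config.fine_cell_m)


# per-layer intercepts: 7 temperature-like (degC), 8 precipitation-like (mm),
# 4 mixtures assembled below
_TEMP_BASE = np.array([8.0, 14.0, 2.0, 18.0, -2.0, 10.0, 5.0])
_PRECIP_BASE = np.array([900.0, 120.0, 60.0, 300.0, 250.0, 80.0, 150.0, 500.0])
_PRECIP_OROG = np.array([450.0, 60.0, 25.0, 160.0, 120.0, 40.0, 70.0, 220.0])
# mixtures: temp share per TEMP_WEIGHTS[15:], precip partner layer and weight
_MIX_PARTNER = [(0, 7), (1, 8), (2, 10), (4, 14)]


def make_bioclim(dem_coarse: RasterGrid, config: LandscapeConfig) -> list[ClimateScenario]:
    """One baseline plus (n_gcm x n_rcp) future scenarios on the coarse grid.

    Temperature-like layers decrease with elevation at the configured lapse
    rate plus smooth correlated noise; precipitation-like layers increase
    orographically; mixture layers are linear blends.  Future layers add the
    rcp warming offset (scaled by each layer's temperature share) and a
    per-GCM, per-layer scalar jitter.
    """
    rng = np.random.default_rng([config.seed, 1])
    elev_km = dem_coarse.data / 1000.0
    shape = dem_coarse.shape
    sigma = max(1.0, min(shape) / 8)

    # a wetness gradient independent of elevation gives the pooled PCA a real
    # second axis (as the moisture axis of real bioclim data does)
    wetness = _smooth_field(rng, shape, max(sigma, min(shape) / 4))

    layers: list[np.ndarray] = []
    for i in range(7):
        noise = _smooth_field(rng, shape, sigma) * 0.3
        layers.append(_TEMP_BASE[i] - config.lapse_rate_K_per_km * elev_km + noise)
    for j in range(8):
        noise = _smooth_field(rng, shape, sigma) * 0.04 * _PRECIP_BASE[j]
        layers.append(
            _PRECIP_BASE[j]
            + _PRECIP_OROG[j] * elev_km
            + 0.30 * _PRECIP_BASE[j] * wetness
            + noise
        )
    for k, (ti, pj) in enumerate(_MIX_PARTNER):
        w = TEMP_WEIGHTS[15 + k]
        noise = _smooth_field(rng, shape, sigma) * 0.2
        layers.append(w * layers[ti] + (1 - w) * 0.01 * layers[pj] + noise)

    def as_scenario(tag: str, offset: float, jitter: np.ndarray, rcp=None, gcm=None):
        stk = [
            dem_coarse.like(layers[i] + offset * TEMP_WEIGHTS[i] + jitter[i])
            for i in range(N_BIOCLIM)
        ]
        return ClimateScenario(tag, stk, rcp=rcp, gcm=gcm)

    out = [as_scenario("baseline", 0.0, np.zeros(N_BIOCLIM))]
    for g, gcm in enumerate(config.gcm_tags):
        jrng = np.random.default_rng([config.seed, 2, g])
        jitter = jrng.normal(0.0, config.gcm_jitter_sd, size=N_BIOCLIM)
        if config.gcm_jitter_sd == 0:
            jitter = np.zeros(N_BIOCLIM)
        for rcp, offset in config.rcp_offsets_K.items():
            out.append(as_scenario(f"{rcp}_{gcm}", offset, jitter, rcp=rcp, gcm=gcm))
    return out


def make_geology_mask(
    dem: RasterGrid, carbonate_fraction: float, seed: int
) -> RasterGrid:
    """Binary carbonate-bedrock mask with spatially autocorrelated patches.

    A smooth Gaussian random field is thresholded at the (1 - fraction)
    quantile, so the realized 1-fraction matches the request up to ties.
    """
    if not 0 < carbonate_fraction <= 1:
        raise ValueError("carbonate_fraction must be in (0, 1]")
    if carbonate_fraction == 1:
        return dem.like(np.ones(dem.shape))
    rng = np.random.default_rng([seed, 3])
    f = _smooth_field(rng, dem.shape, sigma=min(dem.shape) / 10)
    thr = np.quantile(f, 1 - carbonate_fraction)
    return dem.like((f > thr).astype(float))


def true_suitability(
    truth: SpeciesTruth, pc1: RasterGrid, pc2: RasterGrid, geology: RasterGrid
) -> RasterGrid:
    """Gaussian-niche suitability in [0, 1], zero off the carbonate mask."""
    pc1.require_congruent(pc2, "climate axes")
    pc1.require_congruent(geology, "axes and geology")
    c1, c2 = truth.niche_center
    b1, b2 = truth.niche_breadth
    z = ((pc1.data - c1) / b1) ** 2 + ((pc2.data - c2) / b2) ** 2
    suit = np.exp(-0.5 * z) * (geology.data > 0)
    return pc1.like(suit)


def true_range_mask(suitability: RasterGrid, geology: RasterGrid) -> np.ndarray:
    """Boolean 'truly suitable' area: suitability above its median on the mask."""
    on = geology.data > 0
    med = np.nanmedian(suitability.data[on])
    return (suitability.data > med) & on


def make_species(
    truth: SpeciesTruth,
    climate_axes_fine: tuple[RasterGrid, RasterGrid],
    geology: RasterGrid,
    seed: int,
) -> pd.DataFrame:
    """Sample occurrence points proportional to true suitability.

    Cells are drawn with replacement with probability proportional to their
    suitability; each point is jittered uniformly inside its cell.  Returns a
    table with columns species, x, y.
    """
    pc1, pc2 = climate_axes_fine
    suit = true_suitability(truth, pc1, pc2, geology)
    w = np.nan_to_num(suit.data.ravel(), nan=0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"empty niche on landscape for {truth.species_id!r}")
    rng = np.random.default_rng([seed, 4])
    idx = rng.choice(w.size, size=truth.n_occurrences, p=w / total)
    rows, cols = np.unravel_index(idx, suit.shape)
    jx, jy = rng.random(len(idx)), rng.random(len(idx))
    x = suit.x0 + (cols + jx) * suit.cell_m
    y = suit.y0 - (rows + jy) * suit.cell_m
    return pd.DataFrame({"species": truth.species_id, "x": x, "y": y})


def thin_occurrences(points: pd.DataFrame, grid: RasterGrid) -> pd.DataFrame:
    """Keep at most one occurrence per species per grid cell (first in input order).

    Mitigates pseudo-replication before modelling, mirroring occurrence
    resampling at the analysis resolution.
    """
    if points.empty:
        return points.copy()
    row, col = grid.cell_index(points["x"].to_numpy(), points["y"].to_numpy())
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    if not inside.all():
        raise ValueError(f"{(~inside).sum()} occurrence(s) fall outside the grid")
    keyed = points.assign(_row=row, _col=col)
    thinned = keyed.drop_duplicates(subset=["species", "_row", "_col"], keep="first")
    return thinned.drop(columns=["_row", "_col"]).reset_index(drop=True)
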