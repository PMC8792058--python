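"""Climate axes: pooled PCA of the 19 bioclimatic variables, and statistical
downscaling of the two axes to the fine terrain grid by geographically
weighted regression (GWR).

The PCA is fitted once on baseline and all future scenarios pooled together
(after centring and scaling each variable on the pooled sample), then every
scenario is projected with the shared loadings, so axis values are comparable
across climates.  Downscaling regresses each coarse-grid axis locally on five
coarse-aggregated topographic predictors (elevation, slope, northness,
eastness, irradiation) with a Gaussian distance-decay kernel, and applies the
local coefficients to the fine-grid predictor values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .grid import RasterGrid
from .scenarios import ClimateScenario, N_BIOCLIM, TEMP_LIKE
from .terrain_metrics import TerrainStack

__all__ = ["PooledPCAResult", "DownscaleModel", "pooled_pca", "gwr_downscale"]


@dataclass
class PooledPCAResult:
    """Shared two-axis decomposition of the pooled scenario stack."""

    loadings: np.ndarray  # (19, 2); zero rows for dropped constant layers
    explained_variance: np.ndarray  # (2,) fractions of pooled variance
    center: np.ndarray  # (19,)
    scale: np.ndarray  # (19,)
    kept: np.ndarray  # (19,) bool; False for layers dropped as constant
    per_scenario_axes: dict[str, tuple[RasterGrid, RasterGrid]] = field(default_factory=dict)

    def project(self, scenario: ClimateScenario) -> tuple[RasterGrid, RasterGrid]:
        """Score rasters (PC1, PC2) of one scenario under the shared loadings."""
        x = (scenario.stack() - self.center) / self.scale
        scores = np.nan_to_num(x[:, self.kept]) @ self.loadings[self.kept]
        bad = np.isnan(x[:, self.kept]).any(axis=1)
        scores[bad] = np.nan
        shape = scenario.grid.shape
        return (
            scenario.grid.like(scores[:, 0].reshape(shape)),
            scenario.grid.like(scores[:, 1].reshape(shape)),
        )


def pooled_pca(scenarios: list[ClimateScenario]) -> PooledPCAResult:
    """Fit one PCA on all scenarios pooled, project each with shared loadings.

    Variables are standardized on the pooled sample before decomposition
    (bioclim units are heterogeneous); constant variables are dropped with a
    warning.  PC1 is oriented to correlate positively with the mean of the
    temperature-like layers; PC2's largest-magnitude loading is made positive.
    """
    if not scenarios:
        raise ValueError("no scenarios to decompose")
    base = scenarios[0].grid
    for sc in scenarios[1:]:
        base.require_congruent(sc.grid, "scenario grids")
    pooled = np.vstack([sc.stack() for sc in scenarios])  # (n_scen*cells, 19)
    valid = ~np.isnan(pooled).any(axis=1)
    if valid.sum() < 3:
        raise ValueError("too few complete cells for a pooled PCA")
    sample = pooled[valid]
    center = sample.mean(axis=0)
    sd = sample.std(axis=0, ddof=0)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} constant bioclim layer(s) from the PCA")
    scale = np.where(kept, sd, 1.0)
    z = (sample - center) / scale

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z[:, kept])
    loadings = np.zeros((N_BIOCLIM, 2))
    loadings[kept] = pca.components_.T

    # sign conventions
    temp_mean = z[:, list(TEMP_LIKE)].mean(axis=1)
    if np.corrcoef(scores[:, 0], temp_mean)[0, 1] < 0:
        loadings[:, 0] *= -1
    if loadings[np.argmax(np.abs(loadings[:, 1])), 1] < 0:
        loadings[:, 1] *= -1

    result = PooledPCAResult(
        loadings=loadings,
        explained_variance=np.asarray(pca.explained_variance_ratio_),
        center=center,
        scale=scale,
        kept=kept,
    )
    for sc in scenarios:
        result.per_scenario_axes[sc.tag] = result.project(sc)
    return result


@dataclass
class DownscaleModel:
    """GWR configuration plus, after fitting, the per-location coefficients.

    ``bandwidth_m`` defaults to 1.5 coarse cell widths when left None — local
    enough that block-averaging the downscaled field back to the coarse grid
    stays within a few percent of the coarse field, while still pooling the
    immediate neighbourhood; the kernel is Gaussian in distance.  At each fitted location the effective
    sample size (Kish) must reach ``predictors + 2``, otherwise the bandwidth
    is locally widened; a locally singular design falls back to an
    intercept-only (kernel-mean) model with a warning.
    """

    bandwidth_m: float | None = None
    kernel: str = "gaussian"
    predictor_names: tuple[str, ...] = TerrainStack.PREDICTOR_NAMES
    coefficients: np.ndarray | None = None  # (coarse_rows, coarse_cols, 6)
    n_fallback: int = 0

    def weights(self, d: np.ndarray, bw: float) -> np.ndarray:
        if self.kernel == "gaussian":
            return np.exp(-0.5 * (d / bw) ** 2)
        if self.kernel == "bisquare":
            w = (1 - (d / (3 * bw)) ** 2) ** 2
            return np.where(d < 3 * bw, w, 0.0)
        raise ValueError(f"unknown kernel {self.kernel!r}")


def _coarse_predictors(terrain: TerrainStack, factor: int) -> np.ndarray:
    grids = (terrain.elevation, terrain.slope, terrain.northness, terrain.eastness, terrain.dni)
    return np.stack([g.block_aggregate(factor, "mean").data for g in grids], axis=-1)


def gwr_downscale(
    axis_coarse: RasterGrid, terrain_fine: TerrainStack, model: DownscaleModel | None = None
) -> RasterGrid:
    """Downscale one coarse climate axis onto the fine terrain grid.

    Fitting sample: coarse cells (axis value vs block-mean predictors).
    Prediction: each fine cell applies its enclosing coarse cell's local
    coefficients to the fine-grid predictor values.  Fine cells with undefined
    predictors (slope border) use the coarse block means instead, so the
    output is defined wherever the coarse axis is.
    """
    if model is None:
        model = DownscaleModel()
    fine = terrain_fine.elevation
    factor = axis_coarse.cell_m / fine.cell_m
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("fine cell must divide the coarse cell")
    factor = int(round(factor))
    if fine.n_rows != axis_coarse.n_rows * factor or fine.n_cols != axis_coarse.n_cols * factor:
        raise ValueError("terrain and axis extents do not match")
    bw = model.bandwidth_m or 1.5 * axis_coarse.cell_m

    pc = _coarse_predictors(terrain_fine, factor)  # (cr, cc, 5)
    y = axis_coarse.data
    cx, cy = axis_coarse.cell_centers()
    cr, cc = axis_coarse.shape
    ok = ~np.isnan(y) & ~np.isnan(pc).any(axis=-1)
    if ok.sum() < len(model.predictor_names) + 2:
        raise ValueError("too few valid coarse cells to fit the GWR")

    # standardize predictors on the coarse sample for numerical stability
    mu = pc[ok].mean(axis=0)
    sd = pc[ok].std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    zc = (pc - mu) / sd

    pts = np.column_stack([cx[ok], cy[ok]])
    zs = zc[ok]
    ys = y[ok]
    p = zs.shape[1]
    coef = np.full((cr, cc, p + 1), np.nan)
    n_fallback = 0
    min_ess = p + 2

    for i in range(cr):
        for j in range(cc):
            if not ok[i, j]:
                continue
            d = np.hypot(pts[:, 0] - cx[i, j], pts[:, 1] - cy[i, j])
            local_bw = bw
            w = model.weights(d, local_bw)
            # widen the kernel until the effective sample size is adequate
            while w.sum() ** 2 / (w**2).sum() < min_ess and local_bw < 100 * bw:
                local_bw *= 1.5
                w = model.weights(d, local_bw)
            sw = np.sqrt(w)
            # drop locally constant predictors
            wmean = (w[:, None] * zs).sum(0) / w.sum()
            wvar = (w[:, None] * (zs - wmean) ** 2).sum(0) / w.sum()
            use = wvar > 1e-12
            X = np.column_stack([np.ones(len(zs)), zs[:, use]])
            beta, _, rank, _ = np.linalg.lstsq(sw[:, None] * X, sw * ys, rcond=None)
            if rank < X.shape[1]:
                n_fallback += 1
                coef[i, j, 0] = (w * ys).sum() / w.sum()
                coef[i, j, 1:] = 0.0
            else:
                coef[i, j, 0] = beta[0]
                coef[i, j, 1:][use] = beta[1:]
                coef[i, j, 1:][~use] = 0.0
    if n_fallback:
        warnings.warn(f"GWR fell back to intercept-only at {n_fallback} location(s)")
    model.coefficients = coef
    model.n_fallback = n_fallback

    # fine-grid prediction
    zf = np.stack(
        [
            g.data
            for g in (
                terrain_fine.elevation,
                terrain_fine.slope,
                terrain_fine.northness,
                terrain_fine.eastness,
                terrain_fine.dni,
            )
        ],
        axis=-1,
    )
    zf = (zf - mu) / sd
    # fill undefined fine predictors with their coarse block mean
    zc_big = np.repeat(np.repeat(zc, factor, axis=0), factor, axis=1)
    bad = np.isnan(zf)
    zf[bad] = zc_big[bad]
    coef_big = np.repeat(np.repeat(coef, factor, axis=0), factor, axis=1)
    pred = coef_big[..., 0] + np.einsum("ijk,ijk->ij", coef_big[..., 1:], zf)
    return RasterGrid(pred, fine.cell_m, fine.x0, fine.y0)
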