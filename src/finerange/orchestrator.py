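"""End-to-end pipeline: landscape -> terrain -> climate axes -> downscaling ->
ensemble SDMs -> binarization & consensus -> range dynamics -> climate-change
velocity -> category statistics.

All randomness flows from one master seed through named deterministic
sub-streams, so a rerun with the same config reproduces every artifact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binarization_consensus as bc
from . import category_statistics as cs
from . import climate_velocity as cv
from . import range_dynamics as rd
from . import sdm_ensemble as sdm
from .climate_axes import DownscaleModel, PooledPCAResult, gwr_downscale, pooled_pca
from .grid import RasterGrid
from .scenarios import ClimateScenario
from .synthetic_landscape import (
    LandscapeConfig,
    SpeciesTruth,
    make_bioclim,
    make_dem,
    make_geology_mask,
    make_species,
    thin_occurrences,
    true_suitability,
)
from .terrain_metrics import TerrainStack, build_terrain_stack, resample_nearest, tci, tri

log = logging.getLogger("finerange")

__all__ = ["PipelineConfig", "PipelineResult", "SpeciesResult", "check_species_eligibility", "run_pipeline", "default_species"]

MIN_OCCURRENCES = 30  # species need strictly more than this to be modelled


def default_species(pc1: RasterGrid, pc2: RasterGrid) -> list[SpeciesTruth]:
    """Demo community: two modellable virtual endemics plus one too-rare species.

    Niche centers are placed on the cold (high-elevation) side of the baseline
    PC1 distribution — where narrow endemic mountain plants live — expressed
    as quantiles so the community is meaningful for any landscape extent.
    Breadths are fractions of the baseline axis spread, giving each species a
    coherent suitable area covering roughly a quarter of the landscape.
    """
    v1 = pc1.data[~np.isnan(pc1.data)]
    v2 = pc2.data[~np.isnan(pc2.data)]
    s1, s2 = v1.std(), max(v2.std(), 1e-6)
    q = lambda v, f: float(np.quantile(v, f))
    return [
        SpeciesTruth(
            "sp_highalpine",
            niche_center=(q(v1, 0.15), q(v2, 0.5)),
            niche_breadth=(0.8 * s1, 2.0 * s2),
            n_occurrences=150,
        ),
        SpeciesTruth(
            "sp_subalpine",
            niche_center=(q(v1, 0.40), q(v2, 0.5)),
            niche_breadth=(0.9 * s1, 2.0 * s2),
            n_occurrences=80,
        ),
        SpeciesTruth(
            "sp_rare",
            niche_center=(q(v1, 0.25), q(v2, 0.5)),
            niche_breadth=(0.25 * s1, 0.6 * s2),
            n_occurrences=31,
        ),
    ]


@dataclass
class PipelineConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    species: list[SpeciesTruth] | None = None
    carbonate_fraction: float = 0.7
    latitude_deg: float = 46.0
    threshold_methods: tuple[str, ...] = bc.THRESHOLD_METHODS
    gwr_bandwidth_m: float | None = None  # None: 3 coarse cell widths
    bin_shape: tuple[int, int] = cv.DEFAULT_BIN_SHAPE
    delta_years: float = 74.0
    alpha: float = 0.05
    robustness_reps: int = 1000
    tci_block_cells: int = 5  # fine cells per TCI block side
    pa_cap: int | None = None  # cap on regression-family pseudo-absences
    seed: int = 0

    def validate(self) -> None:
        _ = self.landscape  # construction already validates the landscape
        if not 0 < self.carbonate_fraction <= 1:
            raise ValueError("carbonate_fraction must be in (0, 1]")
        if self.delta_years <= 0:
            raise ValueError("delta_years must be positive")
        nr, nc = self.landscape.extent_cells
        if nr % self.tci_block_cells or nc % self.tci_block_cells:
            raise ValueError(
                f"extent {self.landscape.extent_cells} not divisible into "
                f"{self.tci_block_cells}-cell TCI blocks"
            )

    def describe(self) -> dict:
        d = {
            "extent_cells": list(self.landscape.extent_cells),
            "fine_cell_m": self.landscape.fine_cell_m,
            "coarse_factor": self.landscape.coarse_factor,
            "n_gcm": self.landscape.n_gcm,
            "rcps": list(self.landscape.rcp_offsets_K),
            "carbonate_fraction": self.carbonate_fraction,
            "delta_years": self.delta_years,
            "seed": self.seed,
        }
        return d


@dataclass
class SpeciesResult:
    species_id: str
    occurrences: pd.DataFrame
    evaluations: pd.DataFrame
    cutoffs: dict[tuple[str, str], float]  # (family, method) -> cutoff
    suitability: dict[tuple[str, str], RasterGrid]  # (family, scenario tag)
    projections: list[bc.BinaryProjection]
    consensus: dict[str, RasterGrid]  # climate ("baseline" | rcp) -> masked binary
    range_results: dict[str, rd.RangeChangeResult]  # per rcp
    cell_tables: dict[str, pd.DataFrame]  # per rcp
    statistics: dict[str, dict] = field(default_factory=dict)  # per rcp per variable
    true_suitability: RasterGrid | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    dem: RasterGrid
    terrain: TerrainStack
    geology: RasterGrid
    scenarios: list[ClimateScenario]
    pca: PooledPCAResult
    fine_axes: dict[str, tuple[RasterGrid, RasterGrid]]
    tri: RasterGrid
    tci: RasterGrid
    velocity: dict[str, cv.VelocitySurface]  # per rcp
    pearson: pd.DataFrame
    species: dict[str, SpeciesResult]
    skipped_species: list[str]
    elapsed_s: float = 0.0


def check_species_eligibility(occurrences: pd.DataFrame) -> list[str]:
    """Species with strictly more than 30 thinned occurrences."""
    if occurrences.empty:
        return []
    counts = occurrences.groupby("species").size()
    return sorted(counts[counts > MIN_OCCURRENCES].index)


def _downscale_axes(
    pca: PooledPCAResult, terrain: TerrainStack, bandwidth_m: float | None
) -> dict[str, tuple[RasterGrid, RasterGrid]]:
    fine = {}
    for tag, (pc1c, pc2c) in pca.per_scenario_axes.items():
        m1 = DownscaleModel(bandwidth_m=bandwidth_m)
        m2 = DownscaleModel(bandwidth_m=bandwidth_m)
        fine[tag] = (gwr_downscale(pc1c, terrain, m1), gwr_downscale(pc2c, terrain, m2))
    return fine


def _fit_species(
    truth: SpeciesTruth,
    occurrences: pd.DataFrame,
    fine_axes: dict[str, tuple[RasterGrid, RasterGrid]],
    geology: RasterGrid,
    scenarios: list[ClimateScenario],
    cfg: PipelineConfig,
) -> SpeciesResult:
    base_pc1, base_pc2 = fine_axes["baseline"]
    Xp = sdm.extract_axis_values(occurrences, base_pc1, base_pc2)
    keep = ~np.isnan(Xp).any(axis=1)
    Xp = Xp[keep]
    occ = occurrences.loc[keep].reset_index(drop=True)

    n_cells_free = int(np.sum(~np.isnan(base_pc1.data))) - len(occ)
    pa_cap = cfg.pa_cap if cfg.pa_cap is not None else max(100, n_cells_free // 2)
    specs = sdm.default_model_specs(
        seed=sdm.stable_seed("species", cfg.seed, truth.species_id), pa_cap=pa_cap
    )

    records: list[sdm.EvaluationRecord] = []
    suitability: dict[tuple[str, str], RasterGrid] = {}
    cutoffs: dict[tuple[str, str], float] = {}
    for family, spec in specs.items():
        datasets = []
        models = []
        for pa_set in range(spec.pa_sets):
            pas = sdm.sample_pseudo_absences(base_pc1, occ, spec, pa_set)
            Xa = sdm.extract_axis_values(pas, base_pc1, base_pc2)
            Xa = Xa[~np.isnan(Xa).any(axis=1)]
            X = np.vstack([Xp, Xa])
            y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xa))])
            datasets.append((X, y))
        records.extend(sdm.cross_validate(family, datasets, spec))
        # final per-pa-set fits on the full data; projections average over sets
        for tag in fine_axes:
            maps = []
            for pa_set, (X, y) in enumerate(datasets):
                seed = sdm.stable_seed("fit", spec.seed, family, pa_set)
                maps.append(sdm.fit_predict(family, X, y, fine_axes[tag], seed))
            mean_suit = maps[0].like(np.nanmean(np.stack([m.data for m in maps]), axis=0))
            suitability[(family, tag)] = mean_suit
        fam_records = [r for r in records if r.family == family]
        for method in cfg.threshold_methods:
            per_set = [
                float(np.median([r.cutoffs[method] for r in fam_records if r.pa_set == s]))
                for s in range(spec.pa_sets)
            ]
            cutoffs[(family, method)] = float(np.median(per_set))

    projections = []
    for tag in fine_axes:
        sc = next(s for s in scenarios if s.tag == tag)
        for family in specs:
            for method in cfg.threshold_methods:
                rule = bc.ThresholdRule(method, cutoffs[(family, method)])
                grid = bc.binarize(suitability[(family, tag)], rule)
                projections.append(
                    bc.BinaryProjection(
                        grid, algorithm=family, threshold=method,
                        scenario=tag, gcm=sc.gcm, rcp=sc.rcp,
                    )
                )

    rcps = sorted({s.rcp for s in scenarios if s.rcp})
    consensus: dict[str, RasterGrid] = {}
    consensus["baseline"] = bc.apply_geology_mask(
        bc.majority_consensus([p for p in projections if p.scenario == "baseline"]),
        geology,
    )
    for rcp in rcps:
        consensus[rcp] = bc.apply_geology_mask(
            bc.majority_consensus([p for p in projections if p.rcp == rcp]), geology
        )

    range_results: dict[str, rd.RangeChangeResult] = {}
    base_by_combo = {
        (p.algorithm, p.threshold): bc.apply_geology_mask(p.grid, geology)
        for p in projections
        if p.scenario == "baseline"
    }
    for rcp in rcps:
        headline = rd.result_from_maps(consensus["baseline"], consensus[rcp])
        combos = []
        for p in projections:
            if p.rcp != rcp:
                continue
            fut = bc.apply_geology_mask(p.grid, geology)
            base = base_by_combo[(p.algorithm, p.threshold)]
            cat = rd.classify_cells(base, fut)
            rl = int(np.nansum(cat.data == rd.Category.LOSS))
            st = int(np.nansum(cat.data == rd.Category.STABLE))
            rg = int(np.nansum(cat.data == rd.Category.GAIN))
            if rl + st == 0:
                continue  # this combination projects no baseline range
            rc_pct, rl_pct, rg_pct = rd.range_change(rl + st, rl, rg)
            combos.append(
                {
                    "algorithm": p.algorithm, "threshold": p.threshold, "gcm": p.gcm,
                    "rc_pct": rc_pct, "rl_pct": rl_pct, "rg_pct": rg_pct,
                }
            )
        headline.per_combination = pd.DataFrame(combos)
        if combos:
            headline.summary = rd.summarize_combinations(headline.per_combination)
        range_results[rcp] = headline

    evaluations = pd.DataFrame(
        [
            {"family": r.family, "pa_set": r.pa_set, "repeat": r.repeat, "auc": r.auc, "tss": r.tss}
            for r in records
        ]
    )
    suit_truth = true_suitability(truth, base_pc1, base_pc2, geology)
    return SpeciesResult(
        species_id=truth.species_id,
        occurrences=occ,
        evaluations=evaluations,
        cutoffs=cutoffs,
        suitability=suitability,
        projections=projections,
        consensus=consensus,
        range_results=range_results,
        cell_tables={},
        true_suitability=suit_truth,
    )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage on the synthetic landscape; optionally write artifacts."""
    t0 = time.time()
    cfg.validate()
    land = cfg.landscape

    log.info("generating landscape (%s fine cells)", land.extent_cells)
    dem = make_dem(land)
    dem_coarse = dem.block_aggregate(land.coarse_factor, "mean")
    terrain = build_terrain_stack(dem, cfg.latitude_deg)
    geology = make_geology_mask(dem, cfg.carbonate_fraction, land.seed)
    scenarios = make_bioclim(dem_coarse, land)

    log.info("pooled PCA over %d scenarios", len(scenarios))
    pca = pooled_pca(scenarios)
    fine_axes = _downscale_axes(pca, terrain, cfg.gwr_bandwidth_m)

    log.info("terrain heterogeneity indices")
    tri_fine = tri(dem)
    tci_block = tci(dem, cfg.tci_block_cells * land.fine_cell_m)
    tci_fine = resample_nearest(tci_block, land.fine_cell_m)

    log.info("climate-change velocity")
    rcps = sorted(land.rcp_offsets_K)
    velocity: dict[str, cv.VelocitySurface] = {}
    for rcp in rcps:
        ccvs, missing = [], []
        for gcm in land.gcm_tags:
            tag = f"{rcp}_{gcm}"
            binning = cv.bin_climate(fine_axes["baseline"], fine_axes[tag], cfg.bin_shape)
            cls_b = binning.classify(*fine_axes["baseline"])
            cls_f = binning.classify(*fine_axes[tag])
            dist, no_analog = cv.nearest_analog_distance(cls_b, cls_f)
            _, ccv = cv.ccv_transform(dist, cfg.delta_years)
            ccvs.append(ccv)
            missing.append(no_analog)
        velocity[rcp] = cv.average_over_gcms(ccvs, missing, cfg.delta_years)

    covariates = {"elevation": dem, "tri": tri_fine, "tci": tci_fine}
    for rcp in rcps:
        covariates[f"ccv_{rcp}"] = velocity[rcp].ccv
    pearson = cs.pearson_matrix(
        pd.DataFrame({k: g.data.ravel() for k, g in covariates.items()}).dropna()
    )

    log.info("species modelling")
    truths = cfg.species if cfg.species is not None else default_species(*fine_axes["baseline"])
    all_occ = []
    for i, truth in enumerate(truths):
        occ = make_species(
            truth, fine_axes["baseline"], geology,
            seed=sdm.stable_seed("occ", cfg.seed, truth.species_id),
        )
        all_occ.append(occ)
    occurrences = thin_occurrences(pd.concat(all_occ, ignore_index=True), dem)
    eligible = check_species_eligibility(occurrences)
    skipped = sorted({t.species_id for t in truths} - set(eligible))
    for sp in skipped:
        log.info("skipping %s: <= %d occurrences after thinning", sp, MIN_OCCURRENCES)

    species_results: dict[str, SpeciesResult] = {}
    for truth in truths:
        if truth.species_id not in eligible:
            continue
        occ = occurrences[occurrences["species"] == truth.species_id].reset_index(drop=True)
        log.info("fitting %s (%d occurrences)", truth.species_id, len(occ))
        res = _fit_species(truth, occ, fine_axes, geology, scenarios, cfg)
        for rcp in rcps:
            cat_map = res.range_results[rcp].category_map
            covs = {
                "elevation": dem, "tri": tri_fine, "tci": tci_fine,
                "ccv": velocity[rcp].ccv,
            }
            table = cs.build_cell_table(cat_map, covs)
            res.cell_tables[rcp] = table
            res.statistics[rcp] = _category_stats(table, cfg, truth.species_id, rcp)
        species_results[truth.species_id] = res

    result = PipelineResult(
        config=cfg, dem=dem, terrain=terrain, geology=geology, scenarios=scenarios,
        pca=pca, fine_axes=fine_axes, tri=tri_fine, tci=tci_fine, velocity=velocity,
        pearson=pearson, species=species_results, skipped_species=skipped,
        elapsed_s=time.time() - t0,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    log.info("pipeline done in %.1f s", result.elapsed_s)
    return result


def _category_stats(table: pd.DataFrame, cfg: PipelineConfig, species: str, rcp: str) -> dict:
    out: dict[str, dict] = {}
    if table["category"].nunique() < 2:
        return out
    for var in [c for c in table.columns if c != "category"]:
        groups = [g[var].to_numpy(float) for _, g in table.groupby("category")]
        h, p = cs.kruskal_wallis(groups)
        pw = cs.pairwise_mann_whitney(
            table[var].to_numpy(float), table["category"].to_numpy()
        )
        robustness = {}
        for scheme in ("frac10", "frac01", "cap1000"):
            rep = cs.randomization_robustness(
                table, var, scheme=scheme, reps=cfg.robustness_reps, alpha=cfg.alpha,
                seed=sdm.stable_seed("robust", cfg.seed, species, rcp, var, scheme),
            )
            robustness[scheme] = rep.significant
        out[var] = {
            "kruskal_H": h, "kruskal_p": p,
            "pairwise_p": pw.to_dict(),
            "robustness_significant": robustness,
            "robustness_reps": cfg.robustness_reps,
        }
    return out


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    """Plain-text artifacts: .asc rasters, .csv tables, summary .json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.dem.write_ascii(out_dir / "dem.asc")
    result.geology.write_ascii(out_dir / "geology.asc")
    result.tri.write_ascii(out_dir / "tri.asc")
    result.tci.write_ascii(out_dir / "tci.asc")
    for rcp, surf in result.velocity.items():
        surf.ccv.write_ascii(out_dir / f"ccv_{rcp}.asc")
    for tag, (pc1, pc2) in result.fine_axes.items():
        pc1.write_ascii(out_dir / f"pc1_{tag}.asc")
        pc2.write_ascii(out_dir / f"pc2_{tag}.asc")
    summary: dict = {
        "config": result.config.describe(),
        "explained_variance": result.pca.explained_variance.tolist(),
        "pearson": result.pearson.round(4).to_dict(),
        "skipped_species": result.skipped_species,
        "species": {},
        "elapsed_s": round(result.elapsed_s, 2),
    }
    for sp, res in result.species.items():
        res.occurrences.to_csv(out_dir / f"occurrences_{sp}.csv", index=False)
        res.evaluations.to_csv(out_dir / f"evaluations_{sp}.csv", index=False)
        for climate, grid in res.consensus.items():
            grid.write_ascii(out_dir / f"consensus_{sp}_{climate}.asc")
        sp_summary = {}
        for rcp, rr in res.range_results.items():
            rr.category_map.write_ascii(out_dir / f"categories_{sp}_{rcp}.asc")
            if rr.per_combination is not None:
                rr.per_combination.to_csv(
                    out_dir / f"range_combinations_{sp}_{rcp}.csv", index=False
                )
            sp_summary[rcp] = {
                "PR": rr.PR, "RL": rr.RL, "RG": rr.RG,
                "RC_pct": rr.RC_pct, "RL_pct": rr.RL_pct, "RG_pct": rr.RG_pct,
                "combination_summary": None
                if rr.summary is None
                else rr.summary.round(4).to_dict(),
                "statistics": res.statistics.get(rcp, {}),
            }
        summary["species"][sp] = sp_summary
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
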