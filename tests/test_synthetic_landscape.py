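import numpy as np
import pandas as pd
import pytest

from finerange.grid import RasterGrid
from finerange.synthetic_landscape import (
    LandscapeConfig,
    SpeciesTruth,
    make_bioclim,
    make_dem,
    make_geology_mask,
    make_species,
    thin_occurrences,
    true_suitability,
)
from finerange.terrain_metrics import slope_aspect

CFG = LandscapeConfig(extent_cells=(100, 100), seed=7)


def test_dem_range_clamp_and_determinism():
    dem = make_dem(CFG)
    assert dem.data.max() <= CFG.plateau_elevation_m
    assert dem.data.min() >= CFG.valley_elevation_m
    np.testing.assert_array_equal(dem.data, make_dem(CFG).data)


def test_dem_rejects_bad_config():
    with pytest.raises(ValueError):
        LandscapeConfig(extent_cells=(0, 100))
    with pytest.raises(ValueError):
        LandscapeConfig(plateau_elevation_m=500.0, valley_elevation_m=1000.0)


def test_dem_slope_peaks_at_middle_elevations():
    """Valleys and plateaus are flat; the steep flanks sit in between."""
    dem = make_dem(CFG)
    slope, _ = slope_aspect(dem)
    ok = ~np.isnan(slope.data)
    elev, slp = dem.data[ok], slope.data[ok]
    t1, t2 = np.quantile(elev, [1 / 3, 2 / 3])
    med = [
        np.median(slp[elev <= t1]),
        np.median(slp[(elev > t1) & (elev <= t2)]),
        np.median(slp[elev > t2]),
    ]
    assert med[1] == max(med)


def test_bioclim_zero_perturbation_identity():
    cfg = LandscapeConfig(
        extent_cells=(40, 40),
        coarse_factor=20,
        rcp_offsets_K={"rcp45": 0.0},
        gcm_jitter_sd=0.0,
        n_gcm=2,
        seed=3,
    )
    dem_coarse = make_dem(cfg).block_aggregate(cfg.coarse_factor)
    scens = make_bioclim(dem_coarse, cfg)
    base = scens[0]
    for fut in scens[1:]:
        for lb, lf in zip(base.layers, fut.layers):
            np.testing.assert_array_equal(lb.data, lf.data)


def test_bioclim_recovers_lapse_rate():
    dem_coarse = make_dem(CFG).block_aggregate(CFG.coarse_factor)
    base = make_bioclim(dem_coarse, CFG)[0]
    bio1 = base.layers[0].data.ravel()
    elev_km = dem_coarse.data.ravel() / 1000.0
    slope = np.polyfit(elev_km, bio1, 1)[0]
    assert slope == pytest.approx(-CFG.lapse_rate_K_per_km, rel=0.05)


def test_bioclim_future_adds_offset():
    cfg = LandscapeConfig(
        extent_cells=(40, 40), rcp_offsets_K={"rcp85": 4.0}, gcm_jitter_sd=0.0, n_gcm=1, seed=3
    )
    dem_coarse = make_dem(cfg).block_aggregate(cfg.coarse_factor)
    base, fut = make_bioclim(dem_coarse, cfg)
    np.testing.assert_allclose(fut.layers[0].data, base.layers[0].data + 4.0)
    np.testing.assert_allclose(fut.layers[7].data, base.layers[7].data)  # precipitation


def test_geology_mask_fraction_and_determinism():
    dem = make_dem(CFG)
    mask = make_geology_mask(dem, 0.6, seed=11)
    frac = mask.data.mean()
    assert 0.55 <= frac <= 0.65
    np.testing.assert_array_equal(mask.data, make_geology_mask(dem, 0.6, seed=11).data)
    assert make_geology_mask(dem, 1.0, seed=0).data.min() == 1.0
    for bad in (0.0, 1.5, -0.2):
        with pytest.raises(ValueError):
            make_geology_mask(dem, bad, seed=0)


def _toy_axes():
    pc1 = RasterGrid(np.linspace(-3, 3, 100).reshape(10, 10), 50.0)
    pc2 = pc1.like(np.zeros((10, 10)))
    return pc1, pc2


def test_species_occurrences_follow_suitability(rng):
    pc1, pc2 = _toy_axes()
    geology = pc1.like(np.ones((10, 10)))
    truth = SpeciesTruth("sp", niche_center=(0.0, 0.0), niche_breadth=(1.0, 1.0), n_occurrences=500)
    occ = make_species(truth, (pc1, pc2), geology, seed=5)
    suit = true_suitability(truth, pc1, pc2, geology)
    row, col = pc1.cell_index(occ["x"].to_numpy(), occ["y"].to_numpy())
    sampled = suit.data[row, col]
    assert (sampled > 0).all()
    assert sampled.mean() > suit.data.mean()  # suitability-weighted sampling


def test_species_restricted_to_geology_support():
    pc1, pc2 = _toy_axes()
    geo = np.zeros((10, 10))
    geo[4, 7] = 1.0
    geology = pc1.like(geo)
    truth = SpeciesTruth("sp", (0.0, 0.0), (5.0, 5.0), n_occurrences=40)
    occ = make_species(truth, (pc1, pc2), geology, seed=5)
    row, col = pc1.cell_index(occ["x"].to_numpy(), occ["y"].to_numpy())
    assert (row == 4).all() and (col == 7).all()


def test_species_empty_niche_errors():
    pc1, pc2 = _toy_axes()
    geology = pc1.like(np.zeros((10, 10)))
    truth = SpeciesTruth("sp", (0.0, 0.0), (1.0, 1.0), n_occurrences=40)
    with pytest.raises(ValueError, match="empty niche"):
        make_species(truth, (pc1, pc2), geology, seed=5)


def test_species_truth_validates():
    with pytest.raises(ValueError):
        SpeciesTruth("sp", (0, 0), (1, 1), n_occurrences=30)
    with pytest.raises(ValueError):
        SpeciesTruth("sp", (0, 0), (0.0, 1.0), n_occurrences=40)


class TestThinning:
    grid = RasterGrid(np.zeros((10, 10)), cell_m=10.0, x0=0.0, y0=100.0)

    def test_single_cell_collapses_to_one(self):
        pts = pd.DataFrame({"species": "a", "x": np.full(10, 5.0), "y": np.full(10, 95.0)})
        assert len(thin_occurrences(pts, self.grid)) == 1

    def test_distinct_cells_all_kept(self):
        pts = pd.DataFrame(
            {"species": "a", "x": [5.0 + 10 * i for i in range(7)], "y": [95.0] * 7}
        )
        assert len(thin_occurrences(pts, self.grid)) == 7

    def test_keeps_first_point_per_cell(self):
        pts = pd.DataFrame({"species": "a", "x": [2.0, 7.0], "y": [95.0, 95.0]})
        out = thin_occurrences(pts, self.grid)
        assert out["x"].tolist() == [2.0]

    def test_empty_input_gives_empty_output(self):
        out = thin_occurrences(pd.DataFrame(columns=["species", "x", "y"]), self.grid)
        assert out.empty

    def test_matches_occupancy_oracle(self, rng):
        """Thinned size equals the number of occupied (species, cell) pairs."""
        pts = pd.DataFrame(
            {
                "species": rng.choice(["a", "b"], size=200),
                "x": rng.uniform(0, 100, 200),
                "y": rng.uniform(0, 100, 200),
            }
        )
        out = thin_occurrences(pts, self.grid)
        occupied = {
            (sp, int(x // 10), int((100 - y) // 10))
            for sp, x, y in zip(pts["species"], pts["x"], pts["y"])
        }
        assert len(out) == len(occupied)
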