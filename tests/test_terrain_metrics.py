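import numpy as np
import pytest

from finerange.grid import RasterGrid
from finerange.terrain_metrics import (
    dni_proxy,
    northness_eastness,
    resample_nearest,
    slope_aspect,
    tci,
    tri,
)


def plane(nx=12, ny=12, cell=1.0, fx=0.0, fy=0.0, z0=100.0):
    """DEM sampling z = z0 + fx*x + fy*y (x eastward, y northward) at cell centers."""
    g = RasterGrid(np.zeros((ny, nx)), cell_m=cell, x0=0.0, y0=ny * cell)
    x, y = g.cell_centers()
    return g.like(z0 + fx * x + fy * y)


class TestResample:
    def test_constant_stays_constant(self):
        g = RasterGrid(np.full((8, 8), 3.5), 50.0)
        out = resample_nearest(g, 100.0)
        assert out.shape == (4, 4)
        assert (out.data == 3.5).all()

    def test_upsampling_repeats_blocks(self):
        g = RasterGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 100.0)
        out = resample_nearest(g, 50.0)
        np.testing.assert_array_equal(
            out.data, np.array([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]], float)
        )

    def test_roundtrip_values_come_from_source(self, rng):
        g = RasterGrid(rng.normal(size=(12, 12)).cumsum(axis=0), 50.0)
        back = resample_nearest(resample_nearest(g, 150.0), 50.0)
        assert np.isin(back.data, g.data).all()

    def test_incompatible_cell_size_rejected(self):
        g = RasterGrid(np.zeros((4, 4)), 50.0)
        with pytest.raises(ValueError):
            resample_nearest(g, 70.0)


class TestSlopeAspect:
    def test_flat_dem_slope_zero_aspect_zero(self):
        s, a = slope_aspect(RasterGrid(np.full((5, 5), 42.0), 10.0))
        inner = np.s_[1:-1, 1:-1]
        assert np.all(s.data[inner] == 0.0)
        assert np.all(a.data[inner] == 0.0)
        assert a.meta["flat"][inner].all()
        assert np.isnan(s.data[0]).all()  # border is nodata

    def test_eastward_rising_plane(self):
        s, a = slope_aspect(plane(fx=0.5))
        inner = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(s.data[inner], np.arctan(0.5), atol=1e-12)
        np.testing.assert_allclose(a.data[inner], np.pi / 2, atol=1e-12)

    def test_southward_rising_plane_matches_gradient_oracle(self):
        """z = -y: upslope points south (aspect pi), downslope faces north."""
        dem = plane(fy=-1.0)
        s, a = slope_aspect(dem)
        inner = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(a.data[inner], np.pi, atol=1e-12)
        # brute-force central differences agree on a plane
        gx = (dem.data[1:-1, 2:] - dem.data[1:-1, :-2]) / (2 * dem.cell_m)
        gy = (dem.data[:-2, 1:-1] - dem.data[2:, 1:-1]) / (2 * dem.cell_m)
        np.testing.assert_allclose(s.data[inner], np.arctan(np.hypot(gx, gy)), atol=1e-12)

    def test_small_raster_rejected(self):
        with pytest.raises(ValueError):
            slope_aspect(RasterGrid(np.zeros((2, 5)), 10.0))


@pytest.mark.parametrize(
    "aspect,north,east",
    [(0.0, 1.0, 0.0), (np.pi / 2, 0.0, 1.0), (np.pi, -1.0, 0.0)],
)
def test_northness_eastness_cardinal_directions(aspect, north, east):
    a = RasterGrid(np.full((3, 3), aspect), 10.0)
    n, e = northness_eastness(a)
    assert n.data[1, 1] == pytest.approx(north, abs=1e-12)
    assert e.data[1, 1] == pytest.approx(east, abs=1e-12)


def test_northness_eastness_unit_circle(rng):
    a = RasterGrid(rng.uniform(0, 2 * np.pi, (6, 6)), 10.0)
    n, e = northness_eastness(a)
    np.testing.assert_allclose(n.data**2 + e.data**2, 1.0, atol=1e-12)


class TestTRI:
    def test_constant_raster_zero(self):
        assert np.all(tri(RasterGrid(np.full((5, 5), 9.0), 10.0)).data == 0.0)

    def test_center_spike(self):
        z = np.ones((3, 3))
        z[1, 1] = 2.0
        assert tri(RasterGrid(z, 10.0)).data[1, 1] == pytest.approx(1.0)

    def _oracle(self, z):
        out = np.zeros_like(z)
        nr, nc = z.shape
        for i in range(nr):
            for j in range(nc):
                diffs = [
                    abs(z[i, j] - z[i + di, j + dj])
                    for di in (-1, 0, 1)
                    for dj in (-1, 0, 1)
                    if (di, dj) != (0, 0) and 0 <= i + di < nr and 0 <= j + dj < nc
                ]
                out[i, j] = np.mean(diffs)
        return out

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            z = rng.normal(size=(5, 5))
            np.testing.assert_allclose(tri(RasterGrid(z, 10.0)).data, self._oracle(z), atol=1e-12)

    def test_shift_invariance_and_linear_scaling(self, rng):
        z = rng.normal(size=(6, 6))
        g = RasterGrid(z, 10.0)
        np.testing.assert_allclose(tri(g.like(z + 500)).data, tri(g).data, atol=1e-9)
        np.testing.assert_allclose(tri(g.like(2 * z)).data, 2 * tri(g).data, atol=1e-9)


class TestTCI:
    def test_flat_dem_exactly_one(self):
        g = RasterGrid(np.full((10, 10), 1234.0), 10.0)
        assert np.all(tci(g, 50.0).data == 1.0)

    def test_45_degree_plane_sqrt2(self):
        dem = plane(nx=20, ny=20, cell=1.0, fx=1.0)
        out = tci(dem, 5.0)
        np.testing.assert_allclose(out.data, np.sqrt(2.0), atol=1e-6)

    def test_at_least_one_everywhere(self, rng):
        dem = RasterGrid(rng.normal(size=(20, 20)).cumsum(axis=1) * 5, 10.0)
        out = tci(dem, 50.0)
        assert np.nanmin(out.data) >= 1.0

    def test_shift_invariant_but_not_linear(self, rng):
        dem = RasterGrid(rng.normal(size=(12, 12)).cumsum(axis=0) * 10, 10.0)
        base = tci(dem, 60.0).data
        np.testing.assert_allclose(tci(dem.like(dem.data + 100), 60.0).data, base, atol=1e-9)
        doubled = tci(dem.like(dem.data * 2), 60.0).data
        assert not np.allclose(doubled, 2 * base)

    def test_matches_blockwise_oracle(self, rng):
        """Mean of sec(slope) over each coarse block, slope by explicit Horn."""
        z = rng.normal(size=(6, 6)).cumsum(axis=0) * 3
        dem = RasterGrid(z, 10.0)
        out = tci(dem, 30.0)
        sec = np.full((6, 6), np.nan)
        for i in range(1, 5):
            for j in range(1, 5):
                gx = (
                    (z[i - 1, j + 1] + 2 * z[i, j + 1] + z[i + 1, j + 1])
                    - (z[i - 1, j - 1] + 2 * z[i, j - 1] + z[i + 1, j - 1])
                ) / (8 * 10.0)
                gy = (
                    (z[i - 1, j - 1] + 2 * z[i - 1, j] + z[i - 1, j + 1])
                    - (z[i + 1, j - 1] + 2 * z[i + 1, j] + z[i + 1, j + 1])
                ) / (8 * 10.0)
                sec[i, j] = 1.0 / np.cos(np.arctan(np.hypot(gx, gy)))
        for bi in range(2):
            for bj in range(2):
                block = sec[bi * 3 : bi * 3 + 3, bj * 3 : bj * 3 + 3]
                expected = np.nanmean(block)
                assert out.data[bi, bj] == pytest.approx(expected, abs=1e-12)


class TestDNI:
    def test_south_facing_exceeds_north_facing(self):
        slope = RasterGrid(np.full((3, 3), 0.4), 10.0)
        south = RasterGrid(np.zeros((3, 3)), 10.0)  # upslope north = faces south
        north = RasterGrid(np.full((3, 3), np.pi), 10.0)
        assert (
            dni_proxy(slope, south, 46.0).data[0, 0]
            > dni_proxy(slope, north, 46.0).data[0, 0]
        )

    def test_flat_terrain_constant_and_positive(self):
        slope = RasterGrid(np.zeros((4, 4)), 10.0)
        aspect = RasterGrid(np.zeros((4, 4)), 10.0)
        out = dni_proxy(slope, aspect, 46.0).data
        assert np.unique(out).size == 1
        assert (out > 0).all()
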