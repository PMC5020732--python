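"""Spatial primitives: rasterization, focal sums, distances, densities,
slope — each against geometry closed forms or brute-force oracles."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from lurcity.raster import (GridSpec, RasterGrid, euclidean_distance,
                            focal_sum, kernel_density, log_distance,
                            nodata_to_zero, rasterize, slope_from_dem)
from lurcity.vector import VectorLayer


def grid5(n=20, top=100.0):
    return GridSpec(n, n, (0.0, top), 5.0)


class TestRasterize:
    def test_horizontal_line_burns_one_row(self):
        lay = VectorLayer()
        lay.add(LineString([(0, 52.5), (50, 52.5)]))
        r = rasterize(lay, grid5())
        assert r.values.sum() == 10
        assert len(np.unique(np.nonzero(r.values)[0])) == 1

    def test_square_polygon_cell_count(self):
        lay = VectorLayer()
        lay.add(box(0, 0, 100, 100))
        assert rasterize(lay, grid5()).values.sum() == 400

    def test_point_burns_single_cell(self):
        lay = VectorLayer()
        lay.add(Point(12.0, 37.0))
        r = rasterize(lay, grid5())
        assert r.values.sum() == 1
        assert r.values[r.grid.index_of(12, 37)] == 1

    def test_length_weight_mode_conserves_length(self):
        lay = VectorLayer()
        lay.add(LineString([(2, 3), (88, 67)]))
        r = rasterize(lay, grid5(), mode="length_weight")
        assert r.values.sum() == pytest.approx(np.hypot(86, 64), rel=1e-9)

    def test_empty_layer_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning):
            r = rasterize(VectorLayer(), grid5())
        assert not r.values.any()


class TestFocalSum:
    def test_disc_count_at_centre(self):
        ones = RasterGrid(np.ones((21, 21)), (0, 105), 5.0)
        assert focal_sum(ones, 10).values[10, 10] == pytest.approx(13)

    def test_interior_matches_bruteforce_disc_count(self, rng):
        vals = rng.random((15, 15))
        r = RasterGrid(vals, (0, 75), 5.0)
        out = focal_sum(r, 12.0).values
        # brute force: sum over cells whose centre is within the radius
        for (i, j) in [(7, 7), (5, 9), (3, 3)]:
            acc = 0.0
            for a in range(15):
                for b in range(15):
                    if 25 * ((a - i) ** 2 + (b - j) ** 2) <= 144 + 1e-6:
                        acc += vals[a, b]
            assert out[i, j] == pytest.approx(acc, abs=1e-9)

    def test_single_feature_propagates_within_radius(self):
        v = np.zeros((11, 11))
        v[5, 5] = 1.0
        out = focal_sum(RasterGrid(v, (0, 55), 5.0), 15).values
        assert out[5, 5] == 1 and out[5, 8] == 1 and out[5, 9] == 0

    def test_radius_below_cell_size_rejected(self):
        with pytest.raises(ValueError):
            focal_sum(RasterGrid(np.ones((5, 5)), (0, 25), 5.0), 2.0)

    def test_length_and_area_unit_factors(self, small_scene):
        """Buffered road length = pixel count x pixel size; land-use area
        = pixel count x pixel area."""
        import lurcity as L
        comp = L.PPVComputer(small_scene)
        cs = small_scene.grid.cell_size
        spec_t = next(s for s in L.build_catalog() if s.name == "ST.200")
        fs = focal_sum(comp.presence("ST"), 200).values
        assert np.allclose(comp.compute(spec_t).values, fs * cs)
        spec_lu = next(s for s in L.build_catalog() if s.name == "RES.200")
        fs = focal_sum(comp.presence("RES"), 200).values
        assert np.allclose(comp.compute(spec_lu).values, fs * cs * cs)


class TestDistance:
    def test_diagonal_neighbour(self):
        v = np.zeros((5, 5))
        v[0, 0] = 1
        d = euclidean_distance(RasterGrid(v, (0, 25), 5.0))
        assert d.values[1, 1] == pytest.approx(5 * np.sqrt(2))
        assert d.values[0, 0] == 0

    def test_matches_bruteforce_scan(self, rng):
        v = (rng.random((30, 30)) < 0.05).astype(float)
        v[4, 17] = 1  # guarantee at least one feature
        d = euclidean_distance(RasterGrid(v, (0, 150), 5.0)).values
        feats = np.argwhere(v > 0)
        for i in range(30):
            for j in range(30):
                best = np.min(np.hypot(feats[:, 0] - i, feats[:, 1] - j)) * 5
                assert d[i, j] == pytest.approx(best, abs=1e-9)

    def test_no_features_is_an_error(self):
        with pytest.raises(ValueError, match="no feature"):
            euclidean_distance(RasterGrid(np.zeros((4, 4)), (0, 20), 5.0))

    def test_log_distance_epsilon_rule(self):
        v = np.array([[0.0, 95.0]])
        ld = log_distance(RasterGrid(v, (0, 5), 5.0)).values
        assert ld[0, 0] == pytest.approx(np.log(5))
        assert ld[0, 1] == pytest.approx(np.log(100))

    def test_log_distance_preserves_ordering(self, rng):
        v = rng.random((10, 10)) * 500
        r = RasterGrid(v, (0, 50), 5.0)
        ld = log_distance(r).values
        order = np.argsort(v.ravel())
        assert np.all(np.diff(ld.ravel()[order]) >= 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            log_distance(RasterGrid(np.array([[-1.0]]), (0, 5), 5.0))


class TestKernelDensity:
    def test_mass_conservation(self):
        g = GridSpec(200, 200, (0.0, 2000.0), 10.0)
        pts = VectorLayer()
        pts.add(Point(1000, 1000), weight=1000.0)
        kd = kernel_density(pts, 200, g)
        mass = kd.values.sum() * 100 / 1e6  # per-km^2 -> total persons
        assert mass == pytest.approx(1000, rel=0.01)

    def test_zero_weight_gives_zero_field(self):
        g = GridSpec(20, 20, (0.0, 200.0), 10.0)
        pts = VectorLayer()
        pts.add(Point(100, 100), weight=0.0)
        assert not kernel_density(pts, 50, g).values.any()

    def test_linearity_in_weights(self):
        g = GridSpec(40, 40, (0.0, 400.0), 10.0)
        one = VectorLayer()
        one.add(Point(200, 200), weight=500.0)
        two = VectorLayer()
        two.add(Point(200, 200), weight=500.0)
        two.add(Point(200, 200), weight=500.0)
        a = kernel_density(one, 80, g).values
        b = kernel_density(two, 80, g).values
        assert np.allclose(b, 2 * a)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            kernel_density(VectorLayer(), 0.0, grid5())


class TestSlope:
    def test_flat_dem_zero_slope(self):
        dem = RasterGrid(np.full((5, 5), 1200.0), (0, 25), 5.0)
        assert np.allclose(slope_from_dem(dem).values, 0.0)

    def test_unit_gradient_is_45_degrees(self):
        g = GridSpec(10, 10, (0.0, 100.0), 10.0)
        X, _ = g.cell_centers()
        dem = RasterGrid(X.copy(), g.origin, g.cell_size)
        s = slope_from_dem(dem).values
        assert np.allclose(s[1:-1, 1:-1], 45.0)

    def test_matches_direct_horn_formula(self, rng):
        from scipy.ndimage import gaussian_filter
        z = gaussian_filter(rng.standard_normal((12, 12)), 2) * 50
        dem = RasterGrid(z, (0, 60), 5.0)
        s = slope_from_dem(dem).values
        for i in range(1, 11):
            for j in range(1, 11):
                dzdx = ((z[i - 1, j + 1] + 2 * z[i, j + 1] + z[i + 1, j + 1])
                        - (z[i - 1, j - 1] + 2 * z[i, j - 1]
                           + z[i + 1, j - 1])) / 40
                dzdy = ((z[i + 1, j - 1] + 2 * z[i + 1, j] + z[i + 1, j + 1])
                        - (z[i - 1, j - 1] + 2 * z[i - 1, j]
                           + z[i - 1, j + 1])) / 40
                expect = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
                assert s[i, j] == pytest.approx(expect, abs=1e-10)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            slope_from_dem(RasterGrid(np.ones((2, 3)), (0, 10), 5.0))


class TestNodataAndIO:
    def test_nodata_to_zero(self):
        nd = np.zeros((3, 3), bool)
        nd[0, 1] = nd[2, 2] = True
        r = RasterGrid(np.ones((3, 3)), (0, 15), 5.0, nd)
        out = nodata_to_zero(r)
        assert not out.nodata.any()
        assert out.values[0, 1] == 0 and out.values[1, 1] == 1
        # identity without nodata; total unchanged by added zeros
        clean = RasterGrid(np.ones((3, 3)), (0, 15), 5.0)
        assert np.array_equal(nodata_to_zero(clean).values, clean.values)
        assert out.values.sum() == r.values[~nd].sum()

    def test_ascii_roundtrip(self, tmp_path, rng):
        nd = rng.random((6, 7)) < 0.2
        vals = np.round(rng.random((6, 7)) * 100, 4)
        r = RasterGrid(vals, (120.0, 980.0), 5.0, nd)
        r.write_ascii(tmp_path / "r.asc")
        back = RasterGrid.read_ascii(tmp_path / "r.asc")
        assert back.cell_size == 5.0
        assert back.origin == (120.0, 980.0)
        assert np.array_equal(back.nodata, nd)
        assert np.allclose(back.values[~nd], vals[~nd])


def test_translation_equivariance(rng):
    """Shifting the grid origin shifts every output identically."""
    vals = (rng.random((12, 12)) < 0.2).astype(float)
    vals[3, 4] = 1
    for dx, dy in [(1000, -500), (-30, 70)]:
        a = RasterGrid(vals.copy(), (0, 60), 5.0)
        b = RasterGrid(vals.copy(), (dx, 60 + dy), 5.0)
        assert np.allclose(focal_sum(a, 10).values, focal_sum(b, 10).values)
        assert np.allclose(euclidean_distance(a).values,
                           euclidean_distance(b).values)
        assert np.allclose(slope_from_dem(a).values, slope_from_dem(b).values)
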