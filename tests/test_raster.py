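"""Rasterization, filters, classification and composite against
brute-force re-implementations on small grids."""

import math

import numpy as np
import pytest

from lidarstands import raster as ras
from tests.conftest import make_cloud, make_composite


def brute_nearest_rank(values, p):
    s = sorted(values)
    k = max(1, math.ceil(p / 100.0 * len(s)))
    return s[k - 1]


class TestGridMinDem:
    def test_flat_ground(self):
        rng = np.random.default_rng(0)
        cloud = make_cloud(rng.uniform(0, 40, 500), rng.uniform(0, 40, 500), np.full(500, 100.0))
        dem = ras.grid_min_dem(cloud, 4.0, (0, 0, 40, 40))
        assert np.allclose(dem.values, 100.0)

    def test_planar_slope_within_cell_span(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 40, 4000), rng.uniform(0, 40, 4000)
        z = 50.0 + 0.1 * x + 0.05 * y
        dem = ras.grid_min_dem(make_cloud(x, y, z), 4.0, (0, 0, 40, 40))
        xs, ys = dem.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        plane = 50.0 + 0.1 * gx + 0.05 * gy
        span = (0.1 + 0.05) * 4.0  # max elevation change across one cell
        assert np.all(np.abs(dem.values - plane) <= span)

    def test_isolated_empty_cell_filled_with_neighbor_value(self):
        xs, ys = np.meshgrid(np.arange(0.5, 12), np.arange(0.5, 12))
        keep = ~((xs > 4) & (xs < 8) & (ys > 4) & (ys < 8))  # hole in the middle
        cloud = make_cloud(xs[keep], ys[keep], np.full(keep.sum(), 7.0))
        dem = ras.grid_min_dem(cloud, 4.0, (0, 0, 12, 12))
        assert np.allclose(dem.values, 7.0)

    def test_no_ground_points_error(self):
        with pytest.raises(ValueError):
            ras.grid_min_dem(make_cloud([], [], []), 4.0, (0, 0, 8, 8))


class TestNormalizeHeights:
    def test_points_on_dem_have_zero_height(self):
        dem = ras.RasterGrid(np.full((4, 4), 10.0), (0.0, 16.0), 4.0, semantic="elevation_m")
        cloud = make_cloud([2.0, 9.0], [3.0, 14.0], [10.0, 10.0])
        out = ras.normalize_heights(cloud, dem)
        assert np.allclose(out.z, 0.0) and out.normalized

    def test_constant_dem_shift_identity(self):
        dem = ras.RasterGrid(np.full((4, 4), 3.0), (0.0, 16.0), 4.0)
        cloud = make_cloud([5.0], [5.0], [15.5])
        assert ras.normalize_heights(cloud, dem).z[0] == pytest.approx(12.5)

    def test_bilinear_against_brute_force(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 50, (6, 7))
        dem = ras.RasterGrid(vals, (0.0, 24.0), 4.0)
        x = rng.uniform(2.0, 26.0 - 0.001, 200)  # inside the center lattice
        y = rng.uniform(2.001, 22.0, 200)
        got = ras.bilinear_at(dem, x, y)
        xs, ys = dem.cell_centers()
        for xi, yi, gi in zip(x, y, got):
            c = np.searchsorted(xs, xi) - 1
            c = np.clip(c, 0, len(xs) - 2)
            rlist = np.searchsorted(-ys, -yi) - 1  # ys descending
            r = int(np.clip(rlist, 0, len(ys) - 2))
            tx = (xi - xs[c]) / 4.0
            ty = (ys[r] - yi) / 4.0
            ref = (
                vals[r, c] * (1 - tx) * (1 - ty) + vals[r, c + 1] * tx * (1 - ty)
                + vals[r + 1, c] * (1 - tx) * ty + vals[r + 1, c + 1] * tx * ty
            )
            assert gi == pytest.approx(ref, abs=1e-9)

    def test_point_outside_dem_error(self):
        dem = ras.RasterGrid(np.zeros((2, 2)), (0.0, 8.0), 4.0)
        with pytest.raises(ValueError):
            ras.normalize_heights(make_cloud([100.0], [1.0], [5.0]), dem)


class TestHeightPercentileRaster:
    def test_single_return(self):
        cloud = make_cloud([1.0], [1.0], [12.5], normalized=True)
        grid = ras.height_percentile_raster(cloud, (0, 0, 4, 4), 4.0, 85)
        assert grid.values[0, 0] == 12.5

    def test_nearest_rank_oracle_1_to_100(self):
        z = np.arange(1.0, 101.0)
        cloud = make_cloud(np.full(100, 2.0), np.full(100, 2.0), z, normalized=True)
        grid = ras.height_percentile_raster(cloud, (0, 0, 4, 4), 4.0, 85)
        assert grid.values[0, 0] == brute_nearest_rank(z, 85)

    def test_empty_pixel_nodata(self):
        cloud = make_cloud([1.0], [1.0], [5.0], normalized=True)
        grid = ras.height_percentile_raster(cloud, (0, 0, 8, 8), 4.0, 85)
        assert grid.values[1, 1] == grid.nodata

    def test_random_grids_vs_sort_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            x = rng.uniform(0, 16, n)
            y = rng.uniform(0, 16, n)
            z = rng.uniform(0, 30, n)
            p = float(rng.uniform(1, 100))
            cloud = make_cloud(x, y, z, normalized=True)
            grid = ras.height_percentile_raster(cloud, (0, 0, 16, 16), 4.0, p)
            for r in range(4):
                for c in range(4):
                    sel = (np.floor(x / 4).astype(int) == c) & (np.floor((16 - y) / 4).astype(int) == r)
                    if sel.any():
                        assert grid.values[r, c] == brute_nearest_rank(z[sel], p)
                    else:
                        assert grid.values[r, c] == grid.nodata

    def test_percentile_100_is_maximum(self):
        rng = np.random.default_rng(13)
        x, y, z = rng.uniform(0, 8, 300), rng.uniform(0, 8, 300), rng.uniform(0, 20, 300)
        cloud = make_cloud(x, y, z, normalized=True)
        g100 = ras.height_percentile_raster(cloud, (0, 0, 8, 8), 4.0, 100)
        for r in range(2):
            for c in range(2):
                sel = (np.floor(x / 4).astype(int) == c) & (np.floor((8 - y) / 4).astype(int) == r)
                assert g100.values[r, c] == pytest.approx(z[sel].max())


class TestDensityRaster:
    def test_all_ground_zero(self):
        rng = np.random.default_rng(2)
        cloud = make_cloud(rng.uniform(0, 8, 200), rng.uniform(0, 8, 200), np.zeros(200), normalized=True)
        grid = ras.density_raster(cloud, (0, 0, 8, 8), 4.0)
        assert np.allclose(grid.values, 0.0)

    def test_all_canopy_one(self):
        rng = np.random.default_rng(3)
        cloud = make_cloud(rng.uniform(0, 8, 200), rng.uniform(0, 8, 200), np.full(200, 9.0), normalized=True)
        grid = ras.density_raster(cloud, (0, 0, 8, 8), 4.0)
        assert np.allclose(grid.values, 1.0)

    def test_counting_oracle(self):
        z = np.array([0.2] * 7 + [5.0] * 3)
        cloud = make_cloud(np.full(10, 1.0), np.full(10, 1.0), z, normalized=True)
        grid = ras.density_raster(cloud, (0, 0, 4, 4), 4.0)
        assert grid.values[0, 0] == pytest.approx(0.3)

    def test_bounded_in_unit_interval(self, small_normalized, small_scene):
        grid = ras.density_raster(small_normalized, small_scene.config.extent, 4.0)
        valid = grid.values[grid.valid_mask()]
        assert valid.min() >= 0.0 and valid.max() <= 1.0


class TestMedianFilter:
    def test_constant_fixed_point(self):
        g = ras.RasterGrid(np.full((6, 6), 4.2), (0.0, 24.0), 4.0)
        assert np.allclose(ras.median_filter(g).values, 4.2)

    def test_single_outlier_removed(self):
        vals = np.full((5, 5), 2.0)
        vals[2, 2] = 50.0
        g = ras.RasterGrid(vals, (0.0, 20.0), 4.0)
        assert ras.median_filter(g).values[2, 2] == 2.0

    def test_even_window_rejected(self):
        g = ras.RasterGrid(np.zeros((4, 4)), (0.0, 16.0), 4.0)
        with pytest.raises(ValueError):
            ras.median_filter(g, window=4)

    def test_random_grid_vs_brute_force(self):
        rng = np.random.default_rng(21)
        vals = rng.uniform(0, 10, (16, 16))
        g = ras.RasterGrid(vals, (0.0, 64.0), 4.0)
        out = ras.median_filter(g).values
        for r in range(16):
            for c in range(16):
                window = vals[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
                assert out[r, c] == pytest.approx(np.median(window))

    def test_nodata_ignored_and_preserved(self):
        vals = np.full((4, 4), 3.0)
        vals[1, 1] = ras.NODATA
        g = ras.RasterGrid(vals, (0.0, 16.0), 4.0)
        out = ras.median_filter(g).values
        assert out[1, 1] == ras.NODATA
        assert np.allclose(out[out != ras.NODATA], 3.0)


class TestMeanShiftFilter:
    def test_constant_fixed_point(self):
        g = ras.RasterGrid(np.full((8, 8), 1.5), (0.0, 32.0), 4.0)
        assert np.allclose(ras.mean_shift_filter(g, 2.0, 1.0).values, 1.5)

    def test_separated_plateaus_preserved(self):
        vals = np.zeros((8, 8))
        vals[:, 4:] = 10.0
        g = ras.RasterGrid(vals, (0.0, 32.0), 4.0)
        out = ras.mean_shift_filter(g, 2.0, 2.0).values
        assert np.array_equal(out, vals)

    def test_noisy_plateau_converges_to_level(self):
        rng = np.random.default_rng(31)
        vals = 5.0 + rng.uniform(-0.5, 0.5, (16, 16))
        g = ras.RasterGrid(vals, (0.0, 64.0), 4.0)
        out = ras.mean_shift_filter(g, 3.0, 2.0, max_iter=100, tol=1e-6).values
        assert np.all(np.abs(out - out.mean()) < 0.05)
        assert abs(out.mean() - 5.0) < 0.1

    def test_nonpositive_radius_rejected(self):
        g = ras.RasterGrid(np.zeros((4, 4)), (0.0, 16.0), 4.0)
        with pytest.raises(ValueError):
            ras.mean_shift_filter(g, 0.0, 1.0)


class TestMlClassify:
    def test_equal_variance_boundary(self):
        # one band, N(0,1) vs N(10,1): boundary at 5, so 2 -> class 0
        arr = np.array([[[2.0, 6.0]]])
        stats = {"a": (np.array([0.0]), np.array([1.0])), "b": (np.array([10.0]), np.array([1.0]))}
        out = ras.ml_classify(arr, stats, ("a", "b"))
        assert out.values[0, 0] == 0 and out.values[0, 1] == 1

    def test_tie_breaks_to_lowest_index(self):
        arr = np.array([[[5.0]]])
        stats = {"a": (np.array([0.0]), np.array([1.0])), "b": (np.array([10.0]), np.array([1.0]))}
        assert ras.ml_classify(arr, stats, ("a", "b")).values[0, 0] == 0

    def test_pixel_at_class_mean(self):
        arr = np.array([[[20.0]], [[7.0]], [[1.0]]])  # 3 bands, one pixel
        stats = {
            "x": (np.array([20.0, 7.0, 1.0]), np.ones(3)),
            "y": (np.array([40.0, 30.0, 30.0]), np.ones(3)),
        }
        assert ras.ml_classify(arr, stats, ("x", "y")).values[0, 0] == 0

    def test_zero_sd_rejected(self):
        arr = np.zeros((1, 2, 2))
        with pytest.raises(ValueError):
            ras.ml_classify(arr, {"a": (np.array([0.0]), np.array([0.0]))}, ("a",))

    def test_well_separated_classes_high_accuracy(self):
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 3, (100, 100))
        means = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 6.0], [0.0, 12.0, 6.0]])
        arr = np.stack(
            [means[truth, b] + rng.normal(0, 1.0, truth.shape) for b in range(3)]
        )
        stats = {f"c{k}": (means[k], np.ones(3)) for k in range(3)}
        out = ras.ml_classify(arr, stats, ("c0", "c1", "c2"))
        acc = np.mean(out.values == truth)
        assert acc >= 0.99
        confusion = np.zeros((3, 3))
        np.add.at(confusion, (truth.ravel(), out.values.astype(int).ravel()), 1)
        assert ras.kappa_coefficient(confusion) >= 0.98


class TestKappa:
    def test_perfect_agreement(self):
        assert ras.kappa_coefficient(np.diag([10, 20, 30])) == pytest.approx(1.0)

    def test_hand_value(self):
        assert ras.kappa_coefficient([[45, 5], [5, 45]]) == pytest.approx(0.8)

    def test_chance_agreement_zero(self):
        row = np.array([0.6, 0.4])
        col = np.array([0.3, 0.7])
        cm = np.outer(row, col) * 200
        assert ras.kappa_coefficient(cm) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import cohen_kappa_score, confusion_matrix

        rng = np.random.default_rng(6)
        a = rng.integers(0, 3, 500)
        b = np.where(rng.uniform(size=500) < 0.8, a, rng.integers(0, 3, 500))
        ours = ras.kappa_coefficient(confusion_matrix(a, b))
        assert ours == pytest.approx(cohen_kappa_score(a, b), rel=1e-12)

    def test_degenerate_marginal_error(self):
        with pytest.raises(ValueError):
            ras.kappa_coefficient([[5, 0], [0, 0]])


class TestComposite:
    def test_geometry_and_band_count(self):
        comp = make_composite(np.zeros((4, 4)), np.zeros((4, 4)))
        assert comp.shape == (4, 4)
        assert comp.density.same_geometry(comp.classification)

    def test_affine_height_normalization(self):
        comp = make_composite(np.zeros((3, 3)), np.full((3, 3), 10.0), height_range=(0.0, 20.0))
        assert np.allclose(comp.normalized_band(1), 0.5)

    def test_density_identity_when_range_observed(self):
        rng = np.random.default_rng(12)
        d = rng.uniform(0, 1, (5, 5))
        d.flat[0], d.flat[-1] = 0.0, 1.0
        comp = ras.build_composite(
            ras.RasterGrid(d, (0.0, 20.0), 4.0, semantic="density"),
            ras.RasterGrid(np.zeros((5, 5)), (0.0, 20.0), 4.0),
            ras.RasterGrid(np.zeros((5, 5)), (0.0, 20.0), 4.0),
        )
        assert np.allclose(comp.normalized_band(0), d)

    def test_geometry_mismatch_rejected(self):
        a = ras.RasterGrid(np.zeros((4, 4)), (0.0, 16.0), 4.0)
        b = ras.RasterGrid(np.zeros((5, 4)), (0.0, 20.0), 4.0)
        with pytest.raises(ValueError):
            ras.build_composite(a, b, a)


class TestAsciiGridRoundTrip:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        g = ras.RasterGrid(rng.uniform(0, 100, (7, 5)).round(4), (10.0, 38.0), 4.0)
        path = tmp_path / "g.asc"
        ras.write_ascii_grid(g, path)
        back = ras.read_ascii_grid(path)
        assert np.allclose(back.values, g.values, atol=1e-6)
        assert back.origin == pytest.approx(g.origin)
        assert back.pixel_size == g.pixel_size
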