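"""GARGA segmentation operations against brute-force oracles on small
grids, plus end-to-end recovery properties."""

import numpy as np
import pytest

from lidarstands import raster as ras
from lidarstands import segmentation as seg
from lidarstands.params import load_parameter_group
from tests.conftest import make_composite

PARAMS = seg.SegmentationParams()
MERGE = seg.MergeParams()


class TestParams:
    def test_priority_must_end_at_one(self):
        with pytest.raises(ValueError):
            seg.SegmentationParams(priority_function=(0.0, 0.5))

    def test_priority_must_ascend(self):
        with pytest.raises(ValueError):
            seg.SegmentationParams(priority_function=(0.0, 0.5, 0.5, 1.0))

    def test_merge_rounds_must_escalate(self):
        with pytest.raises(ValueError):
            seg.MergeParams(rounds=(((0.2, 2.0, 3.2), (0.02, 2.0, 0.75)),
                                    ((0.05, 1.0, 2.0), (0.0, 1.0, 0.2))))

    def test_published_groups_load(self):
        for n in range(1, 8):
            sp, mp = load_parameter_group(n)
            assert sum(sp.gradient_band_weights) > 0
            assert len(mp.rounds) == 4
            assert mp.maximum_area == 50000.0
            assert mp.small_segment_area == 500.0
        sp1, _ = load_parameter_group(1)
        sp5, _ = load_parameter_group(5)
        assert sp1.competition_threshold == 0.02
        assert sp5.competition_threshold == 0.04
        assert sp5.priority_function == (0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0)


class TestWeightedGradient:
    def test_constant_bands_zero_gradient(self):
        comp = make_composite(np.full((6, 6), 0.4), np.full((6, 6), 8.0))
        g = seg.weighted_gradient(comp, (0.3, 0.3, 0.3))
        assert np.allclose(g.values, 0.0)

    def test_vertical_step_localized(self):
        h = np.zeros((8, 8))
        h[:, 4:] = 1.0
        comp = make_composite(np.zeros((8, 8)), h, height_range=(0.0, 1.0))
        g = seg.weighted_gradient(comp, (0.0, 1.0, 0.0)).values
        nonzero_cols = np.unique(np.nonzero(g)[1])
        assert set(nonzero_cols) == {3, 4}
        assert np.allclose(g[:, :3], 0.0) and np.allclose(g[:, 5:], 0.0)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(2)
        comp = make_composite(rng.uniform(0, 1, (8, 8)), rng.uniform(0, 20, (8, 8)))
        a = seg.weighted_gradient(comp, (0.3, 0.3, 0.3)).values
        b = seg.weighted_gradient(comp, (0.6, 0.6, 0.6)).values
        assert np.allclose(a, b)

    def test_wrong_weight_count(self):
        comp = make_composite(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            seg.weighted_gradient(comp, (1.0, 1.0))


def brute_force_seeds(g, labelmap, level):
    """Independent seed scan: 3x3 local minima under the level, one per
    4-connected equal-valued plateau (row-major first)."""
    nrows, ncols = g.shape
    cand = np.zeros_like(g, dtype=bool)
    for r in range(nrows):
        for c in range(ncols):
            if labelmap[r, c] != 0 or g[r, c] > level:
                continue
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and g[rr, cc] < g[r, c]:
                        ok = False
            cand[r, c] = ok
    seeds = []
    seen = np.zeros_like(cand)
    for r in range(nrows):
        for c in range(ncols):
            if not cand[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < nrows and 0 <= c2 < ncols and cand[r2, c2]
                            and not seen[r2, c2] and g[r2, c2] == g[r, c]):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            seeds.append((r, c))
    return seeds


class TestFindSeeds:
    def test_unique_global_minimum(self):
        g = np.ones((5, 5))
        g[2, 3] = 0.0
        grid = ras.RasterGrid(g, (0.0, 20.0), 4.0, semantic="gradient")
        assert seg.find_seeds(grid, np.zeros((5, 5), int), 0.0) == [(2, 3)]

    def test_constant_above_level_empty(self):
        grid = ras.RasterGrid(np.full((5, 5), 0.6), (0.0, 20.0), 4.0, semantic="gradient")
        assert seg.find_seeds(grid, np.zeros((5, 5), int), 0.3) == []

    def test_random_grids_vs_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            g = rng.uniform(0, 1, (8, 8)).round(1)  # coarse values force plateaus
            labelmap = np.where(rng.uniform(size=(8, 8)) < 0.2, 1, 0)
            level = float(rng.uniform(0, 1))
            grid = ras.RasterGrid(g, (0.0, 32.0), 4.0, semantic="gradient")
            ours = seg.find_seeds(grid, labelmap, level)
            assert set(ours) == set(brute_force_seeds(g, labelmap, level))


class TestRegionGrow:
    def test_homogeneous_single_seed_fills(self):
        comp = make_composite(np.full((6, 6), 0.5), np.full((6, 6), 10.0))
        lm = np.zeros((6, 6), int)
        seg.region_grow(comp, [(0, 0)], PARAMS, lm, bound=0.01)
        assert np.all(lm == 1)

    def test_two_halves_flood_fill_oracle(self):
        d = np.zeros((6, 8))
        d[:, 4:] = 1.0
        comp = make_composite(d, np.zeros((6, 8)))
        lm = np.zeros((6, 8), int)
        seg.region_grow(comp, [(0, 0), (0, 7)], PARAMS, lm, bound=0.05)
        assert np.all(lm[:, :4] == 1) and np.all(lm[:, 4:] == 2)

    def test_zero_bound_annexes_only_identical(self):
        d = np.full((4, 4), 0.5)
        d[0, 1] = 0.6
        comp = make_composite(d, np.zeros((4, 4)))
        lm = np.zeros((4, 4), int)
        seg.region_grow(comp, [(0, 0)], PARAMS, lm, bound=0.0)
        assert lm[0, 1] == 0
        assert lm[3, 3] == 1  # reached around the off pixel

    def test_seed_on_assigned_pixel_rejected(self):
        comp = make_composite(np.zeros((4, 4)), np.zeros((4, 4)))
        lm = np.zeros((4, 4), int)
        lm[1, 1] = 1
        with pytest.raises(ValueError):
            seg.region_grow(comp, [(1, 1)], PARAMS, lm, bound=1.0)


class TestIterativeSegmentation:
    def test_homogeneous_image_single_segment(self):
        comp = make_composite(np.full((10, 10), 0.5), np.full((10, 10), 12.0))
        lm = seg.iterative_segmentation(comp, PARAMS)
        assert np.all(lm == 1)

    def test_k_plateaus_recovered_exactly(self):
        d = np.zeros((12, 12))
        h = np.zeros((12, 12))
        d[:, 4:8], d[:, 8:] = 0.5, 1.0
        h[:, 4:8], h[:, 8:] = 10.0, 20.0
        comp = make_composite(d, h)
        lm = seg.iterative_segmentation(comp, PARAMS)
        ids = np.unique(lm)
        assert ids.size == 3
        for block in (lm[:, :4], lm[:, 4:8], lm[:, 8:]):
            assert np.unique(block).size == 1

    def test_full_cover(self):
        rng = np.random.default_rng(5)
        comp = make_composite(rng.uniform(0, 1, (12, 12)), rng.uniform(0, 20, (12, 12)))
        lm = seg.iterative_segmentation(comp, PARAMS)
        assert np.all(lm > 0)


class TestSegmentStats:
    def test_single_pixel_segment(self):
        comp = make_composite(np.array([[0.25, 0.5], [0.5, 0.5]]), np.array([[3.0, 8.0], [8.0, 8.0]]))
        lm = np.array([[1, 2], [2, 2]])
        st = seg.compute_segment_stats(lm, comp)
        assert st.counts[1] == 1
        assert st.mean(1) == (0.25, 3.0)
        assert st.std(1) == (0.0, 0.0)

    def test_random_labeling_vs_groupby(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 1, (12, 12))
        h = rng.uniform(0, 25, (12, 12))
        lm = rng.integers(1, 6, (12, 12))
        comp = make_composite(d, h)
        st = seg.compute_segment_stats(lm, comp)
        for sid in range(1, 6):
            mask = lm == sid
            assert st.mean(sid)[0] == pytest.approx(d[mask].mean(), abs=1e-12)
            assert st.mean(sid)[1] == pytest.approx(h[mask].mean(), abs=1e-12)
            assert st.std(sid)[0] == pytest.approx(d[mask].std(), abs=1e-12)
            assert st.std(sid)[1] == pytest.approx(h[mask].std(), abs=1e-12)
            assert st.area(sid) == mask.sum() * 16.0

    def test_neighbor_symmetry(self):
        rng = np.random.default_rng(9)
        lm = rng.integers(1, 7, (10, 10))
        comp = make_composite(np.zeros((10, 10)), np.zeros((10, 10)))
        st = seg.compute_segment_stats(lm, comp)
        for a in st.ids():
            for b in st.neighbors[a]:
                assert a in st.neighbors[b]

    def test_uncovered_pixel_rejected(self):
        comp = make_composite(np.zeros((4, 4)), np.zeros((4, 4)))
        lm = np.ones((4, 4), int)
        lm[0, 0] = 0
        with pytest.raises(ValueError):
            seg.compute_segment_stats(lm, comp)


class TestMergePass:
    def test_identical_neighbors_merge(self):
        comp = make_composite(np.full((2, 6), 0.5), np.full((2, 6), 10.0))
        lm = np.repeat(np.array([[1, 1, 1, 2, 2, 2]]), 2, axis=0)
        st = seg.compute_segment_stats(lm, comp)
        seg.merge_pass(lm, st, MERGE.rounds[0], MERGE)
        assert np.unique(lm).size == 1

    def test_all_above_threshold_unchanged(self):
        d = np.repeat(np.array([[0.1, 0.1, 0.9, 0.9]]), 2, axis=0)
        comp = make_composite(d, np.zeros((2, 4)))
        lm = np.repeat(np.array([[1, 1, 2, 2]]), 2, axis=0)
        st = seg.compute_segment_stats(lm, comp)
        before = lm.copy()
        seg.merge_pass(lm, st, MERGE.rounds[3], MERGE)
        assert np.array_equal(lm, before)

    @pytest.mark.parametrize("std_mode", ["increase", "pairwise"])
    def test_collinear_triplet_oracle(self, std_mode):
        # A ~= B but C differs: exactly A+B merge, final count 2
        d = np.repeat(np.array([[0.50, 0.50, 0.52, 0.52, 0.95, 0.95]]), 2, axis=0)
        comp = make_composite(d, np.zeros((2, 6)))
        lm = np.repeat(np.array([[1, 1, 2, 2, 3, 3]]), 2, axis=0)
        merge = seg.MergeParams(std_mode=std_mode)
        st = seg.compute_segment_stats(lm, comp)
        # exhaustive pair enumeration oracle under the same round thresholds
        mean_thr, std_thr = merge.rounds[3]
        admissible_pairs = []
        for a in (1, 2, 3):
            for b in (2, 3):
                if b <= a or b not in st.neighbors[a]:
                    continue
                dmean, dstd = st.band_deltas(a, b, std_mode)
                if np.all(dmean <= mean_thr) and np.all(dstd <= std_thr):
                    admissible_pairs.append((a, b))
        assert admissible_pairs == [(1, 2)]
        seg.merge_pass(lm, st, merge.rounds[3], merge)
        assert np.unique(lm).size == 2
        assert np.unique(lm[:, 4:]).size == 1

    def test_merge_never_increases_count(self):
        rng = np.random.default_rng(12)
        comp = make_composite(rng.uniform(0, 1, (10, 10)), rng.uniform(0, 20, (10, 10)))
        lm = seg.iterative_segmentation(comp, PARAMS)
        st = seg.compute_segment_stats(lm, comp)
        for r in MERGE.rounds:
            before = len(st.counts)
            seg.merge_pass(lm, st, r, MERGE)
            assert len(st.counts) <= before


class TestEnforceMinArea:
    def test_small_segment_absorbed(self):
        # 2 pixels = 32 m^2 < 500 m^2 at 4 m pixels
        comp = make_composite(np.full((4, 4), 0.5), np.full((4, 4), 10.0))
        lm = np.ones((4, 4), int)
        lm[0, :2] = 2
        st = seg.compute_segment_stats(lm, comp)
        seg.enforce_min_area(lm, st, 500.0)
        assert np.all(lm == 1)

    def test_large_segments_untouched(self):
        comp = make_composite(np.zeros((16, 16)), np.zeros((16, 16)))
        lm = np.ones((16, 16), int)
        lm[:, 8:] = 2  # each half is 128 px * 16 m^2 = 2048 m^2
        st = seg.compute_segment_stats(lm, comp)
        before = lm.copy()
        seg.enforce_min_area(lm, st, 500.0)
        assert np.array_equal(lm, before)

    def test_single_segment_scene_unchanged(self):
        comp = make_composite(np.zeros((3, 3)), np.zeros((3, 3)))
        lm = np.ones((3, 3), int)
        st = seg.compute_segment_stats(lm, comp)
        seg.enforce_min_area(lm, st, 500.0)
        assert np.all(lm == 1)


@pytest.fixture(scope="module")
def plateau_composite():
    # three 16x48-pixel plateaus with strong contrasts, mild noise
    rng = np.random.default_rng(3)
    d = np.zeros((48, 48))
    h = np.zeros((48, 48))
    d[:, :16], d[:, 16:32], d[:, 32:] = 0.1, 0.5, 0.9
    h[:, :16], h[:, 16:32], h[:, 32:] = 2.0, 12.0, 24.0
    d += rng.normal(0, 0.02, d.shape)
    h += rng.normal(0, 0.3, h.shape)
    return make_composite(np.clip(d, 0, 1), np.clip(h, 0, None))


class TestSegmentStands:
    def test_plateaus_recovered(self, plateau_composite):
        sp, mp = load_parameter_group(5)
        grid, polygons, st = seg.segment_stands(plateau_composite, sp, mp)
        truth = np.zeros((48, 48), int)
        truth[:, 16:32], truth[:, 32:] = 1, 2
        rep = seg.compare_segmentations(grid.values.astype(int), truth + 1)
        assert rep["adjusted_rand_index"] > 0.95
        assert 3 <= rep["count_a"] <= 6

    def test_deterministic(self, plateau_composite):
        sp, mp = load_parameter_group(5)
        a, _, _ = seg.segment_stands(plateau_composite, sp, mp)
        b, _, _ = seg.segment_stands(plateau_composite, sp, mp)
        assert np.array_equal(a.values, b.values)

    def test_full_partition_and_min_area(self, plateau_composite):
        sp, mp = load_parameter_group(5)
        grid, _, st = seg.segment_stands(plateau_composite, sp, mp)
        labels = grid.values.astype(int)
        assert np.all(labels > 0)
        areas = [st.area(s) for s in st.ids()]
        assert sum(areas) == labels.size * 16.0
        if len(areas) > 1:
            assert min(areas) >= mp.small_segment_area

    def test_polygon_areas_match_pixel_counts(self, plateau_composite):
        sp, mp = load_parameter_group(5)
        grid, polygons, st = seg.segment_stands(plateau_composite, sp, mp)
        for sid, poly in polygons.items():
            assert poly.area == pytest.approx(st.area(sid))


class TestCompareSegmentations:
    def test_identical_maps(self):
        lm = np.repeat(np.arange(1, 5), 4).reshape(4, 4)
        rep = seg.compare_segmentations(lm, lm)
        assert rep["adjusted_rand_index"] == pytest.approx(1.0)
        assert rep["count_difference"] == 0
        assert rep["boundary_precision"] == 1.0 and rep["boundary_recall"] == 1.0

    def test_pair_counting_oracle(self):
        # 1-segment map vs 2x2 blocks on a 4x4 grid: closed-form ARI
        ones = np.ones((4, 4), int)
        blocks = np.array([[1, 1, 2, 2]] * 2 + [[3, 3, 4, 4]] * 2)
        rep = seg.compare_segmentations(ones, blocks)

        def comb2(n):
            return n * (n - 1) // 2

        n = 16
        sum_ab = 4 * comb2(4)  # cells of the contingency table
        sum_a = comb2(16)
        sum_b = 4 * comb2(4)
        expected = sum_a * sum_b / comb2(n)
        maximum = 0.5 * (sum_a + sum_b)
        ari = (sum_ab - expected) / (maximum - expected)
        assert rep["adjusted_rand_index"] == pytest.approx(ari, rel=1e-12)

    def test_symmetry_of_ari(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 4, (8, 8))
        b = rng.integers(1, 4, (8, 8))
        assert seg.compare_segmentations(a, b)["adjusted_rand_index"] == pytest.approx(
            seg.compare_segmentations(b, a)["adjusted_rand_index"]
        )

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError):
            seg.compare_segmentations(np.ones((3, 3), int), np.ones((4, 4), int))
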