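import numpy as np
import pytest

from fibroquant._constants import MUSCLE_WATER
from fibroquant.ct_io import CTSlice
from fibroquant.rule_label import (
    DegenerateBodyError,
    EmptyBodyError,
    RuleParams,
    binarize_body,
    donut_region,
    extract_muscle_water,
    extract_skin,
    kmeans_1d_two,
    label_slice,
    split_fat_fibrosis,
)

PARAMS = RuleParams()


def disk_slice(radius=10, size=32, hu=0.0):
    rr, cc = np.mgrid[0:size, 0:size]
    mask = np.hypot(rr - size / 2, cc - size / 2) <= radius
    return CTSlice(np.where(mask, hu, -1000.0)), mask


class TestBinarizeBody:
    def test_all_air_raises(self):
        with pytest.raises(EmptyBodyError):
            binarize_body(CTSlice(np.full((8, 8), -1000.0)), PARAMS)

    def test_disk_recovered(self):
        sl, mask = disk_slice()
        np.testing.assert_array_equal(binarize_body(sl, PARAMS), mask)

    def test_interior_hole_filled(self):
        sl, mask = disk_slice()
        sl.pixels[16, 16] = -1000.0  # one air pixel inside the body
        np.testing.assert_array_equal(binarize_body(sl, PARAMS), mask)

    def test_small_specks_discarded(self):
        sl, mask = disk_slice()
        sl.pixels[1, 1] = 0.0  # isolated speck away from the body
        np.testing.assert_array_equal(binarize_body(sl, PARAMS), mask)


class TestExtractSkin:
    def test_border_band_of_square(self):
        body = np.zeros((13, 13), dtype=bool)
        body[1:12, 1:12] = True
        skin = extract_skin(body, RuleParams(skin_erosion_radius=1))
        expected = body & ~np.pad(np.ones((9, 9), dtype=bool), 2)
        np.testing.assert_array_equal(skin, expected)

    def test_over_erosion_raises(self):
        body = np.zeros((8, 8), dtype=bool)
        body[3:5, 3:5] = True  # 2x2 object, radius 2 erosion empties it
        with pytest.raises(DegenerateBodyError):
            extract_skin(body, RuleParams(skin_erosion_radius=2))

    def test_skin_and_interior_partition_the_body(self):
        _, body = disk_slice()
        skin = extract_skin(body, PARAMS)
        interior = body & ~skin
        assert not (skin & interior).any()
        np.testing.assert_array_equal(skin | interior, body)


class TestMuscleWaterWindow:
    def test_inclusive_bounds(self):
        hu = np.array([[-50.0, -34.0, 0.0, 26.0, 27.0]])
        interior = np.ones_like(hu, dtype=bool)
        mw = extract_muscle_water(CTSlice(hu), interior, PARAMS)
        np.testing.assert_array_equal(mw, [[False, True, True, True, False]])

    def test_empty_interior_gives_empty_mask(self):
        hu = np.zeros((3, 3))
        assert not extract_muscle_water(CTSlice(hu), np.zeros((3, 3), bool), PARAMS).any()

    def test_fat_interior_below_window(self):
        hu = np.full((3, 3), -80.0)
        assert not extract_muscle_water(CTSlice(hu), np.ones((3, 3), bool), PARAMS).any()

    def test_bone_threshold_reassigns_dense_pixels(self):
        hu = np.array([[200.0, 100.0]])
        interior = np.ones_like(hu, dtype=bool)
        assert not extract_muscle_water(CTSlice(hu), interior, PARAMS).any()
        with_bone = RuleParams(bone_threshold=150.0)
        np.testing.assert_array_equal(
            extract_muscle_water(CTSlice(hu), interior, with_bone), [[True, False]]
        )


class TestDonut:
    def test_partition_identities(self, rng):
        interior = rng.random((16, 16)) < 0.6
        mw = interior & (rng.random((16, 16)) < 0.5)
        donut = donut_region(interior, mw)
        assert donut.sum() + mw.sum() == interior.sum()
        assert not donut_region(interior, interior).any()
        np.testing.assert_array_equal(donut_region(interior, np.zeros_like(mw)), interior)

    def test_subset_violation_raises(self):
        interior = np.zeros((4, 4), bool)
        mw = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            donut_region(interior, mw)


def brute_force_best_split(vals):
    """Exhaustive within-cluster SSE minimization over all thresholds."""
    s = sorted(vals)
    best = None
    for k in range(1, len(s)):
        if s[k - 1] == s[k]:
            continue
        lo, hi = np.array(s[:k]), np.array(s[k:])
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best - 1e-12:
            best = sse
    return best


class TestKMeans1D:
    def test_matches_exhaustive_sse_on_random_multisets(self, rng):
        """Global 1-D 2-means equals brute-force single-threshold search."""
        for _ in range(500):
            n = int(rng.integers(2, 21))
            vals = rng.choice([-90, -80, -75, 0, 20, 35, 40, 45], n).astype(float)
            vals += rng.normal(0, 3, n)
            high, _ = kmeans_1d_two(vals)
            if not high.any() or high.all():
                pytest.fail("degenerate split on non-constant data")
            sse = (
                ((vals[~high] - vals[~high].mean()) ** 2).sum()
                + ((vals[high] - vals[high].mean()) ** 2).sum()
            )
            assert sse == pytest.approx(brute_force_best_split(vals), abs=1e-8)

    def test_simple_multiset(self):
        high, (lo, hi) = kmeans_1d_two(np.array([-80.0, -75.0, 35.0, 40.0]))
        np.testing.assert_array_equal(high, [False, False, True, True])
        assert (lo, hi) == (-77.5, 37.5)

    def test_boundary_is_centroid_midpoint(self, rng):
        vals = rng.normal(0, 50, 50)
        high, (lo, hi) = kmeans_1d_two(vals)
        mid = (lo + hi) / 2
        np.testing.assert_array_equal(high, vals > mid)

    def test_single_value_goes_to_nearer_init_centroid(self):
        high, _ = kmeans_1d_two(np.array([-80.0]), init=(-80.0, 40.0))
        assert not high[0]


class TestSplitFatFibrosis:
    def test_low_cluster_is_fat(self):
        hu = np.array([[-80.0, -75.0, 35.0, 40.0]])
        donut = np.ones_like(hu, dtype=bool)
        fat, fib = split_fat_fibrosis(CTSlice(hu), donut, PARAMS)
        np.testing.assert_array_equal(fat, [[True, True, False, False]])
        np.testing.assert_array_equal(fib, [[False, False, True, True]])

    def test_empty_donut(self):
        fat, fib = split_fat_fibrosis(CTSlice(np.zeros((3, 3))), np.zeros((3, 3), bool), PARAMS)
        assert not fat.any() and not fib.any()

    def test_constant_donut_is_all_fat(self):
        hu = np.full((2, 2), -80.0)
        fat, fib = split_fat_fibrosis(CTSlice(hu), np.ones((2, 2), bool), PARAMS)
        assert fat.all() and not fib.any()

    def test_masks_partition_the_donut(self, rng):
        hu = rng.normal(-20, 60, (16, 16))
        donut = rng.random((16, 16)) < 0.5
        fat, fib = split_fat_fibrosis(CTSlice(hu), donut, PARAMS)
        assert not (fat & fib).any()
        np.testing.assert_array_equal(fat | fib, donut)


class TestLabelSlice:
    def test_five_class_partition(self, small_pair):
        sl, _ = small_pair
        lm = label_slice(sl)
        counts = np.bincount(lm.labels.ravel(), minlength=5)
        assert counts.sum() == sl.pixels.size

    def test_all_air_slice_raises(self):
        with pytest.raises(EmptyBodyError):
            label_slice(CTSlice(np.full((16, 16), -1000.0)))

    def test_phantom_ground_truth_recovered(self, small_pair):
        sl, gt = small_pair
        lm = label_slice(sl, RuleParams(skin_erosion_radius=2))
        assert (lm.labels == gt.labels).mean() >= 0.99

    def test_mw_window_monotone_in_upper_bound(self, small_pair):
        """Raising mw_high never shrinks the muscle/water mask."""
        sl, _ = small_pair
        lo = label_slice(sl, RuleParams(mw_high=26.0))
        hi = label_slice(sl, RuleParams(mw_high=60.0))
        mask_lo = lo.labels == MUSCLE_WATER
        mask_hi = hi.labels == MUSCLE_WATER
        assert (mask_lo <= mask_hi).all()
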