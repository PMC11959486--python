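import numpy as np
import pytest

from synaptoquant import (
    FieldConfig,
    ImageStack,
    LabelVolume,
    bernsen_local_threshold,
    equivalent_sphere_radius,
    intersect_masks,
    label_objects_3d,
    make_field_phantom,
    moments_threshold,
    quantify_receptor_fields,
    rolling_ball_subtract,
)
from synaptoquant.shell_intensity import otsu_threshold

from oracles import brute_bernsen, brute_moments, brute_rolling_ball, flood_fill_label


class TestMomentsThreshold:
    def test_bilevel_threshold_between_classes(self):
        sl = np.array([20.0] * 60 + [200.0] * 40).reshape(10, 10)
        t = moments_threshold(sl)
        assert 20 < t < 200

    def test_matches_independent_tsai_derivation(self, rng):
        sl = rng.gamma(3.0, 20.0, size=(64, 64))
        assert moments_threshold(sl) == pytest.approx(brute_moments(sl), rel=1e-10)

    def test_histogram_only_permutation_invariance(self, rng):
        sl = rng.normal(100, 30, size=(32, 32)).clip(0)
        perm = rng.permutation(sl.ravel()).reshape(sl.shape)
        assert moments_threshold(sl) == moments_threshold(perm)

    def test_constant_slice_raises(self):
        with pytest.raises(ValueError):
            moments_threshold(np.full((8, 8), 5.0))


class TestRollingBall:
    def test_constant_slice_becomes_zero(self):
        out = rolling_ball_subtract(np.full((12, 12), 37.0), 2)
        assert np.allclose(out, 0.0)

    def test_impulse_preserved_plateau_removed(self):
        sl = np.full((15, 15), 50.0)
        sl[7, 7] += 100.0
        out = rolling_ball_subtract(sl, 2)
        assert out[7, 7] > 99.0
        far = out.copy()
        far[6:9, 6:9] = 0
        assert np.allclose(far, 0.0, atol=1e-9)

    def test_gradient_plus_spots_matches_naive_paraboloid(self, rng):
        y, x = np.mgrid[0:16, 0:16]
        sl = 0.5 * (x + y).astype(float)
        for (yy, xx) in [(4, 5), (11, 9), (8, 13)]:
            sl[yy, xx] += 80.0
        out = rolling_ball_subtract(sl, 2)
        assert np.allclose(out, brute_rolling_ball(sl, 2), atol=1e-9)
        assert out.min() >= 0

    def test_wide_high_contrast_object_survives(self):
        # an object wider than the nominal radius keeps its interior
        sl = np.zeros((21, 21))
        y, x = np.mgrid[0:21, 0:21]
        sl[(y - 10) ** 2 + (x - 10) ** 2 <= 16] = 200.0
        out = rolling_ball_subtract(sl, 2)
        assert out[10, 10] > 150.0

    def test_oversized_radius_raises(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.zeros((5, 5)), 3)


class TestBernsen:
    def test_high_contrast_pixels_split_at_midgray(self):
        sl = np.zeros((13, 13))
        sl[6, 5] = 100.0
        sl[6, 6] = 60.0
        sl[6, 8] = 40.0
        out = bernsen_local_threshold(sl, 3, 15.0)
        assert out[6, 6]  # local min 0, max 100 -> midgray 50; 60 > 50
        assert not out[6, 8]  # same window: 40 < 50

    def test_flat_slice_is_single_class(self):
        out = bernsen_local_threshold(np.full((9, 9), 3.0), 4, 10.0)
        assert not out.any()

    def test_matches_bruteforce_evaluation(self, rng):
        sl = rng.gamma(2.0, 30.0, size=(20, 20))
        got = bernsen_local_threshold(sl, 3, 25.0)
        want = brute_bernsen(sl, 3, 25.0, otsu_threshold(sl))
        assert np.array_equal(got, want)


class TestIntersectMasks:
    def _lv(self, arr, geometry):
        return LabelVolume(arr.astype(np.uint8), geometry)

    def test_subset_passes_through(self, geometry, rng):
        first = rng.random((4, 6, 6)) > 0.3
        second = first & (rng.random((4, 6, 6)) > 0.5)
        out = intersect_masks(self._lv(first, geometry), self._lv(second, geometry))
        assert np.array_equal(out.mask, second)

    def test_disjoint_masks_empty(self, geometry):
        a = np.zeros((3, 4, 4), dtype=bool)
        b = np.zeros((3, 4, 4), dtype=bool)
        a[0], b[2] = True, True
        assert not intersect_masks(self._lv(a, geometry), self._lv(b, geometry)).mask.any()

    def test_random_masks_voxelwise_and(self, geometry, rng):
        a = rng.random((4, 5, 5)) > 0.5
        b = rng.random((4, 5, 5)) > 0.5
        out = intersect_masks(self._lv(a, geometry), self._lv(b, geometry)).mask
        for z in range(4):
            for y in range(5):
                for x in range(5):
                    assert out[z, y, x] == (a[z, y, x] and b[z, y, x])

    def test_shape_mismatch_raises(self, geometry):
        with pytest.raises(ValueError):
            intersect_masks(
                self._lv(np.zeros((2, 4, 4)), geometry),
                self._lv(np.zeros((2, 5, 4)), geometry),
            )


class TestLabelObjects:
    def _blob(self, mask, z, y, x, n):
        # lay n voxels in a compact 3D run
        coords = [(z + i // 9, y + (i % 9) // 3, x + i % 3) for i in range(n)]
        for c in coords:
            mask[c] = True

    def test_strict_volume_filter(self, geometry):
        mask = np.zeros((6, 20, 20), dtype=bool)
        self._blob(mask, 1, 2, 2, 12)
        self._blob(mask, 1, 10, 10, 12)
        self._blob(mask, 4, 2, 12, 8)
        objs = label_objects_3d(mask, 10, geometry)
        assert len(objs) == 2
        assert all(o.voxel_count == 12 for o in objs)

    def test_exactly_min_voxels_is_excluded(self, geometry):
        mask = np.zeros((4, 8, 8), dtype=bool)
        self._blob(mask, 1, 2, 2, 10)
        assert label_objects_3d(mask, 10, geometry) == []
        assert len(label_objects_3d(mask, 9, geometry)) == 1

    def test_object_count_matches_flood_fill(self, geometry, rng):
        mask = rng.random((8, 16, 16)) > 0.92
        objs = label_objects_3d(mask, 0, geometry)
        _, n = flood_fill_label(mask, connectivity=26)
        assert len(objs) == n
        assert sum(o.voxel_count for o in objs) == mask.sum()

    def test_volume_and_radius_consistency(self, geometry):
        mask = np.zeros((5, 8, 8), dtype=bool)
        self._blob(mask, 1, 2, 2, 14)
        (obj,) = label_objects_3d(mask, 10, geometry)
        assert obj.volume_um3 == pytest.approx(14 * geometry.voxel_volume_um3)
        assert obj.r_eq_um == pytest.approx(
            equivalent_sphere_radius(obj.volume_um3)
        )


class TestEquivalentSphereRadius:
    def test_unit_sphere(self):
        assert equivalent_sphere_radius(4 * np.pi / 3) == pytest.approx(1.0)

    def test_zero_volume(self):
        assert equivalent_sphere_radius(0.0) == 0.0

    def test_ten_voxel_volume(self):
        assert equivalent_sphere_radius(0.10584) == pytest.approx(0.2935, abs=5e-4)

    def test_negative_volume_raises(self):
        with pytest.raises(ValueError):
            equivalent_sphere_radius(-1.0)


class TestQuantifyReceptorFields:
    def test_noise_free_spheres_recovered_within_ten_percent(self, fine_geometry):
        stack, truth = make_field_phantom(
            [0.3, 0.5, 0.8], geometry=fine_geometry, seed=31
        )
        objs = quantify_receptor_fields(stack)
        assert len(objs) == 3
        vv = fine_geometry.voxel_volume_um3
        got = sorted(o.r_eq_um for o in objs)
        want = sorted(
            equivalent_sphere_radius(c * vv) for c in truth.field_voxel_counts
        )
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=0.10)

    def test_fields_outside_hrp_envelope_are_excluded(self, fine_geometry):
        stack, truth = make_field_phantom(
            [0.5, 0.5, 0.5], geometry=fine_geometry, outside_envelope=1, seed=32
        )
        objs = quantify_receptor_fields(stack)
        assert len(objs) == 2
        # the excluded sphere is the right-most one
        max_x_kept = max(o.centroid[2] for o in objs)
        assert max_x_kept < truth.field_centers[-1][2] - 0.5

    def test_repeat_runs_identical(self, fine_geometry):
        stack, _ = make_field_phantom([0.5, 0.8], geometry=fine_geometry, snr=50, seed=33)
        a = quantify_receptor_fields(stack)
        b = quantify_receptor_fields(stack)
        assert a == b

    def test_enlarging_fields_increases_median_radius(self, fine_geometry):
        small, _ = make_field_phantom([0.35, 0.45], geometry=fine_geometry, seed=34)
        large, _ = make_field_phantom([0.55, 0.75], geometry=fine_geometry, seed=34)
        med = lambda objs: np.median([o.r_eq_um for o in objs])
        assert med(quantify_receptor_fields(large)) > med(quantify_receptor_fields(small))

    def test_intensity_scaling_leaves_segmentation_unchanged(self, fine_geometry):
        stack, _ = make_field_phantom([0.5, 0.8], geometry=fine_geometry, seed=35)
        scaled = ImageStack(
            stack.data * np.array([1.0, 3.0])[:, None, None, None],
            fine_geometry,
            stack.channel_names,
        )
        a = quantify_receptor_fields(stack)
        b = quantify_receptor_fields(scaled)
        assert [o.voxel_count for o in a] == [o.voxel_count for o in b]

    def test_volume_conservation_against_truth(self, fine_geometry):
        stack, truth = make_field_phantom([0.5, 0.8], geometry=fine_geometry, seed=36)
        objs = quantify_receptor_fields(stack)
        assert sum(o.voxel_count for o in objs) <= sum(truth.field_voxel_counts) + 5
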