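"""Geometry core: rim sampling, plane fitting, correction, integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trayvol.geometry import (
    BinaryMask,
    CorrectedDepthMap,
    DegeneratePlaneFitError,
    DepthMap,
    PlaneModel,
    Polarity,
    RimUnavailableError,
    correct_depth,
    fit_base_plane,
    fit_plane,
    integrate_volume,
    normalize_polarity,
    sample_rim,
)


def disk_mask(size: int, center: tuple[float, float], radius: float) -> BinaryMask:
    y, x = np.mgrid[0:size, 0:size].astype(float)
    return BinaryMask((x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2,
                      label="plate")


class TestSampleRim:
    def test_band_width_one_is_the_4_connected_boundary(self):
        # independent boundary definition: mask pixels with a 4-neighbor outside
        mask = disk_mask(9, (4, 4), 3.5)
        m = mask.values
        padded = np.pad(m, 1)
        interior = (
            padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
        ) & m
        expected = m & ~interior
        pts = sample_rim(mask, band_width=1)
        got = np.zeros_like(m)
        got[pts[:, 1], pts[:, 0]] = True
        np.testing.assert_array_equal(got, expected)

    def test_rectangle_band_two_counts(self):
        # 10x10 filled rectangle: 2-px band leaves a 6x6 interior -> 64 band pixels
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        pts = sample_rim(BinaryMask(m), band_width=2)
        assert len(pts) == 100 - 36

    def test_row_major_deterministic_order(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        pts = sample_rim(BinaryMask(m), band_width=1)
        order = pts[:, 1] * 8 + pts[:, 0]
        assert np.all(np.diff(order) > 0)

    def test_fully_covered_plate_raises(self):
        plate = disk_mask(9, (4, 4), 3.5)
        food = BinaryMask(np.ones((9, 9), bool), label="food")
        with pytest.raises(RimUnavailableError, match="rim unavailable"):
            sample_rim(plate, band_width=1, exclusion_masks=[food])

    def test_empty_plate_raises(self):
        with pytest.raises(RimUnavailableError):
            sample_rim(BinaryMask(np.zeros((5, 5), bool)), band_width=1)

    def test_exclusion_removes_food_pixels(self):
        plate = disk_mask(21, (10, 10), 9)
        food = np.zeros((21, 21), bool)
        food[1:6, 8:13] = True  # bite into the top of the rim
        pts = sample_rim(plate, band_width=2, exclusion_masks=[BinaryMask(food)])
        got = set(map(tuple, pts))
        for x, y in got:
            assert not food[y, x]

    def test_large_band_subsampled_with_stride(self):
        plate = disk_mask(101, (50, 50), 48)
        full = sample_rim(plate, band_width=10, max_points=None)
        thinned = sample_rim(plate, band_width=10, max_points=500)
        stride = int(np.ceil(len(full) / 500))
        np.testing.assert_array_equal(thinned, full[::stride])


class TestFitPlane:
    def test_exact_recovery_of_noiseless_plane(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 50)
        y = rng.uniform(0, 100, 50)
        z = 0.1 * x - 0.05 * y + 0.3
        plane = fit_plane(np.column_stack([x, y, z]))
        assert plane.a == pytest.approx(0.1, abs=1e-9)
        assert plane.b == pytest.approx(-0.05, abs=1e-9)
        assert plane.c == pytest.approx(0.3, abs=1e-9)
        assert plane.rms_residual < 1e-9
        assert plane.n_points == 50

    def test_horizontal_plane(self):
        pts = np.array([[0, 0, 0.42], [5, 1, 0.42], [2, 7, 0.42], [9, 3, 0.42]])
        plane = fit_plane(pts)
        assert (plane.a, plane.b, plane.c) == pytest.approx((0, 0, 0.42), abs=1e-12)

    @pytest.mark.parametrize(
        "pts",
        [
            np.array([[0, 0, 1], [1, 1, 2]]),  # too few
            np.array([[0, 0, 1], [1, 1, 2], [2, 2, 3]]),  # collinear
            np.array([[i, 2 * i, i * 0.1] for i in range(10)]),  # collinear, many
        ],
    )
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(DegeneratePlaneFitError, match="degenerate plane fit"):
            fit_plane(pts)

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(-0.1, 0.1),
        b=st.floats(-0.1, 0.1),
        c=st.floats(-1, 1),
        seed=st.integers(0, 2**16),
    )
    def test_planar_data_recovered_exactly(self, a, b, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 200, 30)
        y = rng.uniform(0, 200, 30)
        pts = np.column_stack([x, y, a * x + b * y + c])
        try:
            plane = fit_plane(pts)
        except DegeneratePlaneFitError:  # astronomically unlikely collinear draw
            return
        assert plane.a == pytest.approx(a, abs=1e-9)
        assert plane.b == pytest.approx(b, abs=1e-9)
        assert plane.c == pytest.approx(c, abs=1e-9)


class TestCorrectDepth:
    def test_zero_plane_is_identity(self):
        depth = DepthMap(np.random.default_rng(0).uniform(0, 1, (6, 7)))
        out = correct_depth(depth, PlaneModel(0, 0, 0), clip=False)
        np.testing.assert_array_equal(out.values, depth.values)

    def test_uniform_depth_minus_matching_offset_is_zero(self):
        out = correct_depth(DepthMap(np.full((4, 4), 0.5)), PlaneModel(0, 0, 0.5),
                            clip=False)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_clip_flag_controls_negative_values(self):
        depth = DepthMap(np.full((3, 3), 0.3))
        plane = PlaneModel(0, 0, 0.5)
        clipped = correct_depth(depth, plane, clip=True)
        unclipped = correct_depth(depth, plane, clip=False)
        np.testing.assert_allclose(clipped.values, 0.0)
        np.testing.assert_allclose(unclipped.values, -0.2)
        assert clipped.clipped and not unclipped.clipped

    def test_x_is_column_index(self):
        depth = DepthMap(np.zeros((2, 3)))
        out = correct_depth(depth, PlaneModel(1.0, 0.0, 0.0), clip=False)
        np.testing.assert_allclose(out.values, -np.array([[0, 1, 2], [0, 1, 2]], float))

    def test_wrong_polarity_rejected(self):
        depth = DepthMap(np.zeros((2, 2)), polarity=Polarity.LOWER_IS_ELEVATED)
        with pytest.raises(ValueError, match="polarity"):
            correct_depth(depth, PlaneModel(0, 0, 0))


class TestIntegrateVolume:
    def _corrected(self, values, pixel_area=1.0, clipped=False):
        return CorrectedDepthMap(np.asarray(values, float), PlaneModel(0, 0, 0),
                                 pixel_area=pixel_area, clipped=clipped)

    def test_uniform_prisms(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        est = integrate_volume(self._corrected(np.full((4, 4), 2.0)), BinaryMask(mask))
        assert est.volume == pytest.approx(8.0)
        assert est.n_pixels == 4

    def test_nonpositive_values_contribute_nothing(self):
        values = np.full((5, 5), -1.0)
        values[0, 0] = 0.0
        est = integrate_volume(self._corrected(values), BinaryMask(np.ones((5, 5), bool)))
        assert est.volume == 0.0
        assert est.n_pixels == 0

    def test_empty_mask_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty mask"):
            est = integrate_volume(
                self._corrected(np.ones((3, 3))), BinaryMask(np.zeros((3, 3), bool))
            )
        assert est.volume == 0.0 and est.n_pixels == 0

    def test_pixel_area_scales_volume_exactly(self, rng):
        values = rng.normal(0, 1, (32, 32))
        mask = BinaryMask(rng.random((32, 32)) < 0.4)
        v1 = integrate_volume(self._corrected(values, pixel_area=1.0), mask).volume
        v2 = integrate_volume(self._corrected(values, pixel_area=2.0), mask).volume
        assert v2 == pytest.approx(2.0 * v1, rel=1e-14)

    def test_matches_brute_force_loop_exactly(self, rng):
        # independent oracle: plain python per-pixel accumulation
        for _ in range(10):
            h, w = rng.integers(4, 64, 2)
            values = rng.normal(0, 1, (h, w))
            mask = rng.random((h, w)) < 0.5
            s2 = float(rng.uniform(0.5, 2.0))
            expected, n = 0.0, 0
            for i in range(h):
                for j in range(w):
                    if mask[i, j] and values[i, j] > 0:
                        expected += values[i, j] * s2
                        n += 1
            est = integrate_volume(self._corrected(values, pixel_area=s2),
                                   BinaryMask(mask))
            assert est.volume == pytest.approx(expected, rel=1e-12, abs=1e-12)
            assert est.n_pixels == n

    def test_spherical_cap_within_2_percent_of_closed_form(self):
        # cap h=20 of sphere R=50, rasterized at pixel centers on 512x512
        R, h = 50.0, 20.0
        size = 512
        y, x = np.mgrid[0:size, 0:size].astype(float)
        d2 = (x - size / 2) ** 2 + (y - size / 2) ** 2
        base_r2 = R**2 - (R - h) ** 2
        field = np.where(d2 <= base_r2, np.sqrt(np.maximum(R**2 - d2, 0)) - (R - h), 0.0)
        est = integrate_volume(self._corrected(field), BinaryMask(field > 0))
        analytic = math.pi * h**2 * (R - h / 3)
        assert analytic == pytest.approx(54454.27, abs=0.5)
        assert abs(est.volume - analytic) / analytic < 0.02

    def test_raising_masked_depth_never_decreases_volume(self, rng):
        values = rng.normal(0, 1, (16, 16))
        mask = rng.random((16, 16)) < 0.5
        base = integrate_volume(self._corrected(values), BinaryMask(mask)).volume
        for _ in range(20):
            i, j = rng.integers(0, 16, 2)
            if not mask[i, j]:
                continue
            bumped = values.copy()
            bumped[i, j] += float(rng.uniform(0, 2))
            v = integrate_volume(self._corrected(bumped), BinaryMask(mask)).volume
            assert v >= base - 1e-12


class TestNormalizePolarity:
    def test_identity_when_already_target(self):
        depth = DepthMap(np.array([[0.1, 0.9]]))
        out = normalize_polarity(depth, Polarity.HIGHER_IS_ELEVATED)
        assert out is depth

    def test_flip_maps_max_minus_value(self):
        depth = DepthMap(np.array([[0.1, 0.9]]), polarity=Polarity.LOWER_IS_ELEVATED)
        out = normalize_polarity(depth, Polarity.HIGHER_IS_ELEVATED)
        np.testing.assert_allclose(out.values, [[0.8, 0.0]])
        assert out.polarity is Polarity.HIGHER_IS_ELEVATED

    def test_constant_map_flips_to_zero(self):
        depth = DepthMap(np.full((3, 3), 0.2), polarity=Polarity.LOWER_IS_ELEVATED)
        out = normalize_polarity(depth, Polarity.HIGHER_IS_ELEVATED)
        np.testing.assert_allclose(out.values, 0.0)

    def test_double_flip_preserves_relief(self, rng):
        values = rng.uniform(0, 1, (8, 8))
        depth = DepthMap(values, polarity=Polarity.LOWER_IS_ELEVATED)
        back = normalize_polarity(
            normalize_polarity(depth, Polarity.HIGHER_IS_ELEVATED),
            Polarity.LOWER_IS_ELEVATED,
        )
        # relief (differences) is preserved even though the offset may shift
        np.testing.assert_allclose(back.values - back.values.min(),
                                   values - values.min(), atol=1e-12)


class TestFitBasePlane:
    def test_recovers_scene_tilt_from_rim(self, cap_scene):
        plane = fit_base_plane(cap_scene.depth, cap_scene.truth.plate_mask,
                               exclusion_masks=list(cap_scene.truth.masks.values()))
        assert plane.a == pytest.approx(0.02, abs=1e-9)
        assert plane.b == pytest.approx(-0.01, abs=1e-9)
        assert plane.c == pytest.approx(0.3, abs=1e-9)


class TestValidation:
    def test_depth_map_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            DepthMap(np.array([[np.nan, 1.0]]))

    def test_depth_map_rejects_bad_pixel_area(self):
        with pytest.raises(ValueError, match="pixel_area"):
            DepthMap(np.zeros((2, 2)), pixel_area=0.0)

    def test_volume_estimate_rejects_negative(self):
        from trayvol.geometry import VolumeEstimate

        with pytest.raises(ValueError):
            VolumeEstimate(-1.0)
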