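import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freqalign.align import (
    Aligner,
    CrossCorrelationMatrix,
    correct_angle,
    estimate_rotation,
    estimate_shift,
    joint_align,
    peak_to_shifts,
    polar_spectrum,
    refine_peak,
    rotation_cross_correlation,
    translation_cross_correlation,
)
from freqalign.classify import similarity
from freqalign.imageops import rotate_image, shift_image
from freqalign.synthetic import perturb

from oracles import exhaustive_rotation


class TestCorrectAngle:
    @pytest.mark.parametrize("raw,expected", [
        (350.0, -10.0),
        (180.0, 180.0),
        (0.0, 0.0),
        (180.1, -179.9),
        (90.0, 90.0),
    ])
    def test_folding(self, raw, expected):
        assert correct_angle(raw) == pytest.approx(expected)

    @pytest.mark.parametrize("raw", [-0.1, 360.0, 400.0])
    def test_rejects_out_of_range(self, raw):
        with pytest.raises(ValueError):
            correct_angle(raw)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=359.999))
    def test_range_and_equivalence(self, raw):
        out = correct_angle(raw)
        assert -180.0 <= out <= 180.0
        assert (out - raw) % 360.0 == pytest.approx(0.0, abs=1e-9)


class TestPeakToShifts:
    @pytest.mark.parametrize("x,y,m,expected", [
        (65.0, 65.0, 128, (0.0, 0.0)),
        (60.0, 70.0, 128, (5.0, -5.0)),
        (64.7, 65.0, 128, (0.3, 0.0)),
    ])
    def test_mapping(self, x, y, m, expected):
        dx, dy = peak_to_shifts(x, y, m)
        assert (dx, dy) == pytest.approx(expected)


class TestRefinePeak:
    def test_on_node_quadratic_peak_stays_on_node(self):
        yy, xx = np.indices((30, 30), dtype=float)
        surf = -((yy - 14) ** 2 + (xx - 17) ** 2)
        peak = refine_peak(CrossCorrelationMatrix(surf))
        assert peak.row == pytest.approx(14.0, abs=1e-9)
        assert peak.col == pytest.approx(17.0, abs=1e-9)

    def test_gaussian_bump_subgrid_recovery(self):
        r0, c0 = 14.3, 16.8
        yy, xx = np.indices((30, 30), dtype=float)
        surf = np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * 3.0**2))
        peak = refine_peak(CrossCorrelationMatrix(surf))
        assert peak.row == pytest.approx(r0, abs=0.05)
        assert peak.col == pytest.approx(c0, abs=0.05)

    def test_refined_within_half_unit_of_coarse(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            surf = rng.normal(size=(25, 25))
            pr, pc = np.unravel_index(np.argmax(surf), surf.shape)
            peak = refine_peak(CrossCorrelationMatrix(surf))
            assert abs(peak.row - pr) <= 0.5
            assert abs(peak.col - pc) <= 0.5

    def test_wrapping_peak_near_column_zero(self):
        r0, c0 = 10.0, 0.4  # peak wraps across the angular seam
        yy = np.arange(20, dtype=float)[:, None]
        xx = np.arange(360, dtype=float)[None, :]
        dc = (xx - c0 + 180.0) % 360.0 - 180.0
        surf = np.exp(-((yy - r0) ** 2 + dc**2) / (2 * 2.0**2))
        peak = refine_peak(CrossCorrelationMatrix(surf), wrap_cols=True)
        assert peak.col == pytest.approx(c0, abs=0.05)

    def test_flat_patch_reports_degenerate(self):
        surf = np.ones((20, 20))
        peak = refine_peak(CrossCorrelationMatrix(surf))
        assert peak.degenerate
        assert peak.row == 0.0 and peak.col == 0.0

    def test_interpolant_passes_through_grid_maximum(self, phantom128):
        c = translation_cross_correlation(phantom128, shift_image(phantom128, 2.5, 0))
        peak = refine_peak(c)
        assert peak.patch.max() >= c.values.max() - 1e-9


class TestCrossCorrelation:
    def test_rotational_shape(self, phantom128):
        f = polar_spectrum(phantom128)
        assert rotation_cross_correlation(f, f).shape == (64, 360)

    def test_rotational_self_peak_at_zero_degrees(self, phantom128):
        f = polar_spectrum(phantom128)
        c = rotation_cross_correlation(f, f).values
        assert np.unravel_index(np.argmax(c), c.shape)[1] == 0

    def test_rotational_values_non_negative(self, phantom128):
        f1 = polar_spectrum(phantom128)
        f2 = polar_spectrum(rotate_image(phantom128, 30.0))
        assert rotation_cross_correlation(f1, f2).values.min() >= 0.0

    def test_rotational_peak_column_encodes_angle(self, phantom128):
        f1 = polar_spectrum(phantom128)
        f2 = polar_spectrum(rotate_image(phantom128, 30.0))
        c = rotation_cross_correlation(f1, f2).values
        col = np.unravel_index(np.argmax(c), c.shape)[1]
        # rotating the test image by +30 puts the correction peak at -30
        assert col in (329, 330, 331)

    def test_shape_mismatch_rejected(self, phantom128):
        f = polar_spectrum(phantom128)
        with pytest.raises(ValueError, match="shapes differ"):
            rotation_cross_correlation(f, f[:, :100])

    def test_translational_self_peak_at_center(self, phantom128):
        c = translation_cross_correlation(phantom128, phantom128).values
        assert c.shape == (128, 128)
        assert np.unravel_index(np.argmax(c), c.shape) == (64, 64)

    def test_translational_integer_peak(self, phantom128):
        shifted = shift_image(phantom128, 5, -3)
        c = translation_cross_correlation(phantom128, shifted).values
        row, col = np.unravel_index(np.argmax(c), c.shape)
        dx, dy = peak_to_shifts(col + 1.0, row + 1.0, 128)
        assert (dx, dy) == (5.0, -3.0)


class TestEstimators:
    def test_rotation_self_alignment(self, phantom128):
        assert estimate_rotation(phantom128, phantom128) == 0.0

    def test_rotation_recovery(self, phantom256):
        test = rotate_image(phantom256, -37.4)
        assert estimate_rotation(phantom256, test) == pytest.approx(37.4, abs=0.5)

    def test_rotation_without_interpolation_is_integer(self, phantom128):
        test = rotate_image(phantom128, -37.4)
        est = estimate_rotation(phantom128, test, interpolate=False)
        assert est == int(est)
        assert est == pytest.approx(37.4, abs=1.0)

    def test_rotation_agrees_with_real_space_search(self, phantom64):
        test = rotate_image(phantom64, -52.0)
        iaf = estimate_rotation(phantom64, test, interpolate=False)
        assert iaf == exhaustive_rotation(phantom64, test)

    def test_rotation_antisymmetry(self, phantom128):
        rotated = rotate_image(phantom128, 23.0)
        ab = estimate_rotation(phantom128, rotated)
        ba = estimate_rotation(rotated, phantom128)
        assert abs(((ab + ba) + 180.0) % 360.0 - 180.0) < 0.2

    def test_rotation_estimates_are_tenth_degree_multiples(self, phantom128):
        for angle in (-37.4, 112.3, 5.0):
            est = estimate_rotation(phantom128, rotate_image(phantom128, angle))
            assert round(est * 10.0) == pytest.approx(est * 10.0, abs=1e-9)

    def test_shift_self_alignment(self, phantom128):
        assert estimate_shift(phantom128, phantom128) == (0.0, 0.0)

    def test_shift_recovery(self, phantom128):
        test = shift_image(phantom128, -4.3, 8.1)
        dx, dy = estimate_shift(phantom128, test)
        assert dx == pytest.approx(4.3, abs=0.5)
        assert dy == pytest.approx(-8.1, abs=0.5)

    def test_constant_image_rejected(self, phantom128):
        with pytest.raises(ValueError, match="constant"):
            estimate_rotation(phantom128, np.zeros((128, 128)))
        with pytest.raises(ValueError, match="constant"):
            Aligner(np.ones((64, 64)))


class TestJointAlign:
    def test_self_alignment_converges_immediately(self, phantom128):
        params, aligned = joint_align(phantom128, phantom128)
        assert (params.theta, params.dx, params.dy) == (0.0, 0.0, 0.0)
        assert params.n_iter <= 2
        assert params.converged

    def test_shift_then_rotate_recovery(self, phantom256):
        test = perturb(phantom256, 25.0, 3.0, -2.0)
        params, aligned = joint_align(phantom256, test)
        assert params.theta == pytest.approx(-25.0, abs=0.5)
        assert params.dx == pytest.approx(-3.0, abs=0.5)
        assert params.dy == pytest.approx(2.0, abs=0.5)
        assert params.n_iter <= 10
        # alignment must improve the correlation with the reference
        assert similarity(phantom256, aligned) > similarity(phantom256, test)

    def test_rejects_bad_max_iter(self, phantom128):
        with pytest.raises(ValueError, match="max_iter"):
            joint_align(phantom128, phantom128, max_iter=0)

    def test_interpolated_params_on_tenth_grid(self, phantom128):
        test = perturb(phantom128, -73.3, 2.1, 1.4)
        params, _ = joint_align(phantom128, test)
        assert round(params.theta * 10.0) == pytest.approx(params.theta * 10.0,
                                                           abs=1e-6)
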