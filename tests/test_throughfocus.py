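import numpy as np
import pytest

from multifocal import (
    EyeRecord,
    MetricsReport,
    ThroughFocusCurve,
    ZernikeCoefficients,
    area_under_curve,
    combine_with_eye,
    default_vergence_grid,
    defocus_coeff_from_diopters,
    equivalent_sphere_shift,
    metrics_report,
    normalize_to_monofocal,
    peak_performance,
    range_above_threshold,
    through_focus_curve,
    with_equivalent_sphere,
)
from multifocal.throughfocus import RANGE_SAMPLE_WEIGHT_D, area_weighted_d

from test_segmentation import constant_profile


def synthetic_curve(values, vergences=None):
    v = default_vergence_grid() if vergences is None else np.asarray(vergences)
    return ThroughFocusCurve(v, np.asarray(values, dtype=float))


class TestVergenceGrid:
    def test_canonical_sampling(self):
        g = default_vergence_grid()
        assert g.size == 193
        assert g[0] == -1.0 and g[-1] == 5.0
        steps = np.diff(g)
        assert np.allclose(steps, 6.0 / 192.0)
        assert steps[0] == pytest.approx(0.03125)
        assert g[32] == pytest.approx(0.0, abs=1e-12)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            ThroughFocusCurve(np.array([0.0, 1.0, 1.5]), np.zeros(3))
        with pytest.raises(ValueError):
            ThroughFocusCurve(np.array([1.0, 0.0]), np.zeros(2))


class TestOpticalSweeps:
    def test_clean_eye_flat_lens_peaks_at_zero(self, grid128, clean_eye, flat_profile):
        asm = combine_with_eye(flat_profile, clean_eye, grid=grid128)
        curve = through_focus_curve(asm, vergences=np.linspace(-1, 1, 17))
        peak, loc = peak_performance(curve)
        assert loc == pytest.approx(0.0)
        assert peak == pytest.approx(1.0, abs=1e-4)

    def test_defocus_parity(self, grid128, clean_eye, flat_profile):
        """For a symmetric aberration-free pupil the curve is even in d."""
        asm = combine_with_eye(flat_profile, clean_eye, grid=grid128)
        curve = through_focus_curve(asm, vergences=np.linspace(-1, 1, 9))
        assert np.allclose(curve.values, curve.values[::-1], rtol=1e-9)

    def test_defocused_eye_peak_cancellation(self, grid128, flat_profile):
        """An eye with -0.50 D equivalent defocus peaks at +0.50 D."""
        r = 2.06
        z = ZernikeCoefficients({4: defocus_coeff_from_diopters(-0.5, r)}, r)
        eye = EyeRecord(z, 2 * r, "defocused")
        asm = combine_with_eye(flat_profile, eye, grid=grid128)
        curve = through_focus_curve(asm)
        _, loc = peak_performance(curve)
        assert abs(loc - 0.5) <= 6.0 / 192.0 + 1e-12

    @pytest.mark.parametrize("injected", [-0.8, -0.3, 0.2, 0.6, 1.0])
    def test_peak_location_recovers_injected_defocus(
        self, injected, grid128, clean_eye, flat_profile
    ):
        """Estimator recovery: a defocus-only eye peaks at its injected
        equivalent sphere, within one grid step."""
        eye = with_equivalent_sphere(clean_eye, injected)
        asm = combine_with_eye(flat_profile, eye, grid=grid128)
        curve = through_focus_curve(asm)
        _, loc = peak_performance(curve)
        assert abs(loc - injected) <= 6.0 / 192.0 + 1e-12

    def test_callable_builder_path_matches_fast_path(self, grid128, flat_profile):
        from multifocal.segmentation import build_multifocal_wavefront
        from multifocal.zernike import wavefront_from_coeffs

        R = 2.06
        verg = np.linspace(-0.5, 0.5, 5)

        def builder(d):
            z = ZernikeCoefficients({4: defocus_coeff_from_diopters(d, R)}, R)
            return wavefront_from_coeffs(z, grid128)

        slow = through_focus_curve(builder, vergences=verg)
        asm = build_multifocal_wavefront(flat_profile, R, grid=grid128)
        fast = through_focus_curve(asm, vergences=verg)
        assert np.allclose(slow.values, fast.values, rtol=1e-9)


class TestEquivalentSphereShift:
    def test_peak_already_centered(self):
        values = np.exp(-0.5 * ((default_vergence_grid() - 0.0) / 0.5) ** 2)
        assert equivalent_sphere_shift(synthetic_curve(values)) == 0.0

    def test_shift_opposes_peak_location(self):
        values = np.exp(-0.5 * ((default_vergence_grid() - 0.5) / 0.5) ** 2)
        assert equivalent_sphere_shift(synthetic_curve(values)) == pytest.approx(-0.5)

    def test_tie_broken_toward_smallest_vergence(self):
        assert equivalent_sphere_shift(synthetic_curve(np.ones(193))) == pytest.approx(
            0.0
        )

    def test_optical_shift_recovery_and_recentering(
        self, grid128, clean_eye, flat_profile
    ):
        """Injecting -0.75 D equivalent sphere yields shift +0.75 D, and
        re-sweeping with the shift re-centers the peak at 0.00 D."""
        eye = with_equivalent_sphere(clean_eye, -0.75)
        asm = combine_with_eye(flat_profile, eye, grid=grid128)
        raw = through_focus_curve(asm)
        shift = equivalent_sphere_shift(raw)
        step = 6.0 / 192.0
        assert abs(shift - 0.75) <= step + 1e-12
        recentered = through_focus_curve(asm, shift_d=shift)
        _, loc = peak_performance(recentered)
        assert abs(loc) <= step + 1e-12


class TestMetrics:
    def test_area_is_plain_sum(self):
        assert area_under_curve(synthetic_curve(np.ones(193))) == 193.0
        assert area_under_curve(synthetic_curve(np.zeros(193))) == 0.0
        assert area_under_curve(synthetic_curve(np.full(193, 0.5))) == 96.5

    def test_area_weighted_variant(self):
        assert area_weighted_d(synthetic_curve(np.ones(193))) == pytest.approx(6.0)

    def test_area_warns_on_noncanonical_grid(self):
        curve = synthetic_curve(np.ones(5), vergences=np.linspace(-1, 1, 5))
        with pytest.warns(UserWarning):
            area_under_curve(curve)

    def test_range_counting(self):
        assert range_above_threshold(synthetic_curve(np.ones(193))) == pytest.approx(
            6.0
        )
        assert range_above_threshold(synthetic_curve(np.zeros(193))) == 0.0
        values = np.zeros(193)
        values[:96] = 0.5
        assert range_above_threshold(synthetic_curve(values)) == pytest.approx(
            96 * 6.0 / 193.0
        )

    def test_threshold_equality_excluded(self):
        values = np.full(193, 0.12)
        assert range_above_threshold(synthetic_curve(values), 0.12) == 0.0

    def test_range_weight_is_literal_6_over_193(self):
        # the per-sample weight is 6/193 D even though the step is 6/192 D
        assert RANGE_SAMPLE_WEIGHT_D == pytest.approx(6.0 / 193.0)
        assert RANGE_SAMPLE_WEIGHT_D != pytest.approx(6.0 / 192.0)

    def test_range_monotone_in_curve_and_threshold(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(0, 0.4, size=193)
        curve = synthetic_curve(base)
        lifted = synthetic_curve(base + rng.uniform(0, 0.1, size=193))
        assert range_above_threshold(lifted) >= range_above_threshold(curve)
        assert range_above_threshold(curve, 0.08) >= range_above_threshold(curve, 0.12)

    def test_peak_and_tie_rule(self):
        peak, loc = peak_performance(synthetic_curve(np.full(193, 0.3)))
        assert peak == 0.3 and loc == pytest.approx(0.0)
        values = np.zeros(193)
        values[100] = 0.9
        peak, loc = peak_performance(synthetic_curve(values))
        assert peak == 0.9
        assert loc == pytest.approx(default_vergence_grid()[100])

    def test_metrics_invariant_under_axis_reversal(self):
        g = default_vergence_grid()
        sym = np.exp(-0.5 * ((g - 2.0) / 0.8) ** 2)  # symmetric about mid-grid
        curve = synthetic_curve(sym)
        rev = synthetic_curve(sym[::-1])
        assert area_under_curve(curve) == pytest.approx(area_under_curve(rev))
        assert range_above_threshold(curve) == pytest.approx(range_above_threshold(rev))
        assert peak_performance(curve)[0] == pytest.approx(peak_performance(rev)[0])


class TestNormalization:
    def make_report(self, area, range_d, peak):
        return MetricsReport(
            area=area,
            area_weighted_D=area * RANGE_SAMPLE_WEIGHT_D,
            range_D=range_d,
            peak=peak,
            peak_location_D=0.0,
        )

    def test_self_normalization_is_100(self):
        m = self.make_report(100.0, 3.0, 0.8)
        out = normalize_to_monofocal(m, m)
        assert out.normalized == pytest.approx(
            {"area_pct": 100.0, "range_pct": 100.0, "peak_pct": 100.0}
        )

    def test_ratio_arithmetic(self):
        ref = self.make_report(100.0, 3.0, 0.8)
        m = self.make_report(100.0, 3.0 * 1.29, 0.8 * 0.78)
        out = normalize_to_monofocal(m, ref)
        assert out.normalized["range_pct"] == pytest.approx(129.0)
        assert out.normalized["peak_pct"] == pytest.approx(78.0)

    def test_zero_reference_rejected(self):
        ref = self.make_report(100.0, 0.0, 0.8)
        with pytest.raises(ZeroDivisionError):
            normalize_to_monofocal(self.make_report(1, 1, 1), ref)


class TestCurveIO:
    def test_csv_roundtrip(self, tmp_path):
        curve = ThroughFocusCurve(
            default_vergence_grid(),
            np.linspace(0, 1, 193),
            {"lens": "demo", "eye_id": "e1", "shift_D": -0.25},
        )
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = ThroughFocusCurve.from_csv(path)
        assert np.allclose(back.vergences_d, curve.vergences_d)
        assert np.allclose(back.values, curve.values)
        assert back.meta["lens"] == "demo"
        assert back.meta["shift_D"] == -0.25

    def test_metrics_report_json(self, tmp_path):
        curve = ThroughFocusCurve(default_vergence_grid(), np.full(193, 0.5))
        report = metrics_report(curve)
        path = tmp_path / "metrics.json"
        report.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["area"] == 96.5
        assert data["range_D"] == pytest.approx(6.0)
        assert data["peak"] == 0.5
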