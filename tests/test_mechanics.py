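import math

import numpy as np
import pytest

from ringmech import mechanics, synthdata
from ringmech.mechanics import (
    CurveTooShortError,
    NeverInTensionError,
    StressStrainCurve,
    detect_failure,
    detect_tension_onset,
    elliptical_area,
    subtract_drag,
    summarize,
    tangent_modulus_profile,
    to_stress_strain,
)


def linear_curve(modulus=20.0, n=500, span=0.30):
    eps = np.linspace(0.0, span, n)
    return StressStrainCurve(eng_strain=eps, eng_stress=modulus * eps,
                             gauge_length=5.0, a0=0.3)


class TestTensionOnset:
    def test_first_sample_above_5_mn(self, trace_factory, protocol):
        trace = trace_factory([1, 3, 4, 6, 9])
        onset, gauge = detect_tension_onset(trace, protocol)
        assert onset == 3

    def test_gauge_length_adds_onset_extension(self, trace_factory, protocol):
        trace = trace_factory([1, 3, 4, 6, 9])
        trace.extension = np.array([0.0, 0.005, 0.010, 0.015, 0.020])
        onset, gauge = detect_tension_onset(trace, protocol)
        assert gauge == pytest.approx(5.015)

    def test_never_in_tension(self, trace_factory, protocol):
        with pytest.raises(NeverInTensionError):
            detect_tension_onset(trace_factory([1, 2, 3, 4, 5]), protocol)


class TestDragSubtraction:
    def test_identical_baseline_gives_zero(self, trace_factory):
        trace = trace_factory([3, 7, 12])
        baseline = trace_factory([3, 7, 12], is_baseline=True)
        corrected = subtract_drag(trace, baseline)
        np.testing.assert_allclose(corrected.load, 0.0, atol=1e-15)

    def test_constant_offset(self, trace_factory):
        corrected = subtract_drag(
            trace_factory([3, 7, 12]), trace_factory([2, 2, 2], is_baseline=True)
        )
        np.testing.assert_allclose(corrected.load * 1000, [1, 5, 10])

    def test_coarse_baseline_matches_interpolation_oracle(self, trace_factory):
        # dense trace, baseline on every 4th extension point
        rng = np.random.default_rng(7)
        n = 101
        trace = trace_factory(rng.uniform(5, 50, n))
        base_loads = np.linspace(0.5, 2.0, n)[::4]
        baseline = trace_factory(np.zeros(len(base_loads)), is_baseline=True)
        baseline.extension = trace.extension[::4]
        baseline.time = trace.time[::4]
        baseline.load = base_loads / 1000.0
        corrected = subtract_drag(trace, baseline)
        oracle = trace.load - np.interp(
            trace.extension, baseline.extension, baseline.load
        )
        np.testing.assert_allclose(corrected.load, oracle, rtol=1e-12)

    def test_insufficient_coverage_rejected(self, trace_factory):
        trace = trace_factory(np.arange(100.0))
        baseline = trace_factory(np.zeros(40), is_baseline=True)  # covers 40%
        with pytest.raises(ValueError, match="covers"):
            subtract_drag(trace, baseline)

    def test_non_baseline_rejected(self, trace_factory):
        with pytest.raises(ValueError):
            subtract_drag(trace_factory([1, 2]), trace_factory([1, 2]))


class TestEllipticalArea:
    def test_circle_special_case(self):
        assert elliptical_area(1.0, 1.0) == pytest.approx(math.pi / 4)

    def test_closed_form(self):
        assert elliptical_area(0.8, 0.6) == pytest.approx(0.12 * math.pi)

    @pytest.mark.parametrize("w,h", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_dimension_rejected(self, w, h):
        with pytest.raises(ValueError):
            elliptical_area(w, h)


class TestStressStrainConversion:
    def test_eq2_factor_two_for_ring_limbs(self, trace_factory):
        trace = trace_factory([200.0, 200.0])  # 0.2 N
        curve = to_stress_strain(trace, 0, 5.0, 0.25)
        assert curve.eng_stress[0] == pytest.approx(0.4)

    def test_true_strain_identities(self):
        curve = StressStrainCurve(
            eng_strain=np.array([0.0, math.e - 1.0]),
            eng_stress=np.array([0.0, 1.0]),
            gauge_length=5.0, a0=0.3,
        )
        np.testing.assert_allclose(curve.true_strain, [0.0, 1.0], rtol=1e-14)

    def test_true_stress_at_half_strain(self):
        curve = StressStrainCurve(
            eng_strain=np.array([0.0, 0.5]), eng_stress=np.array([0.0, 2.0]),
            gauge_length=5.0, a0=0.3,
        )
        assert curve.true_stress[1] == pytest.approx(3.0, abs=1e-15)

    def test_identities_hold_elementwise_on_generated_curves(self, geometry, protocol):
        params = synthdata.ConstitutiveParams(
            linear_modulus=12.0, uts=1.5, noise_sd=0.5, seed=3
        )
        trace = synthdata.gen_trace(params, geometry, protocol)
        onset, gauge = detect_tension_onset(trace, protocol)
        curve = to_stress_strain(trace, onset, gauge, geometry.a0_min)
        np.testing.assert_allclose(
            curve.true_strain, np.log(1.0 + curve.eng_strain), rtol=1e-12, atol=1e-15
        )
        np.testing.assert_allclose(
            curve.true_stress, curve.eng_stress * (1.0 + curve.eng_strain),
            rtol=1e-12, atol=1e-15,
        )

    def test_strain_rereferenced_to_onset(self, trace_factory):
        trace = trace_factory([1, 2, 6, 10, 20])
        curve = to_stress_strain(trace, 2, 5.0, 0.3)
        assert curve.eng_strain[0] == 0.0
        assert len(curve) == 3


class TestTangentModulusProfile:
    def test_exact_line_every_slope_equals_modulus(self):
        prof = tangent_modulus_profile(linear_curve(20.0))
        slopes = [w.slope for w in prof]
        np.testing.assert_allclose(slopes, 20.0, rtol=1e-9)

    def test_quadratic_closed_form_maximum(self):
        # sigma = 100 eps^2 on [0, 0.30]: continuous LS slope over the last
        # window [0.22, 0.30] is 100*(0.22 + 0.30) = 52 MPa
        eps = np.linspace(0.0, 0.30, 1000)
        curve = StressStrainCurve(eng_strain=eps, eng_stress=100 * eps**2,
                                  gauge_length=5.0, a0=0.3)
        prof = tangent_modulus_profile(curve)
        mtm = max(w.slope for w in prof)
        assert mtm == pytest.approx(52.0, rel=0.01)

    def test_full_span_window_equals_global_ols(self):
        rng = np.random.default_rng(5)
        eps = np.linspace(0.0, 0.2, 400)
        sigma = 30 * eps + rng.normal(0, 0.05, eps.size)
        curve = StressStrainCurve(eng_strain=eps, eng_stress=sigma,
                                  gauge_length=5.0, a0=0.3)
        prof = tangent_modulus_profile(curve, window_strain=0.2)
        assert len(prof) == 1
        global_slope = np.polyfit(eps, sigma, 1)[0]
        assert prof[0].slope == pytest.approx(global_slope, rel=1e-9)

    def test_short_curve_is_an_error_naming_span(self):
        with pytest.raises(CurveTooShortError, match="span"):
            tangent_modulus_profile(linear_curve(span=0.05))

    def test_window_with_fewer_than_three_samples_skipped(self):
        eps = np.array([0.0, 0.08])
        curve = StressStrainCurve(eng_strain=eps, eng_stress=20 * eps,
                                  gauge_length=5.0, a0=0.3)
        with pytest.raises(CurveTooShortError):
            tangent_modulus_profile(curve)


class TestFailureDetection:
    def test_forty_percent_drop_rule(self):
        idx, detected = detect_failure([10, 50, 100, 58])
        assert (idx, detected) == (3, True)

    def test_monotone_loads_no_failure(self):
        idx, detected = detect_failure([10, 20, 30, 40])
        assert (idx, detected) == (3, False)

    def test_thirty_percent_drop_is_not_failure(self):
        idx, detected = detect_failure([100, 70])
        assert detected is False

    def test_exact_threshold_is_not_failure(self):
        # 60 is not strictly below 60% of 100
        _, detected = detect_failure([100, 60])
        assert detected is False

    def test_noise_floor_cannot_trigger(self):
        # dips while the running max is far below the record peak are ignored
        loads = [5, 1, 5, 50, 100, 30]
        idx, detected = detect_failure(loads)
        assert (idx, detected) == (5, True)

    def test_unconfirmed_single_sample_dip_ignored(self):
        idx, detected = detect_failure([50, 100, 55, 100, 110])
        assert detected is False


class TestSummarize:
    def test_round_trip_with_generator_zero_noise(self, geometry, protocol):
        params = synthdata.ConstitutiveParams(linear_modulus=25.0, uts=3.0)
        trace = synthdata.gen_trace(params, geometry, protocol)
        summary, _ = mechanics.analyze_trace(trace, None, protocol, geometry.a0_min)
        assert summary.mtm == pytest.approx(25.0, rel=0.02)
        assert summary.uts == pytest.approx(3.0, rel=0.01)
        assert summary.failure_strain == pytest.approx(params.rupture_strain, abs=0.01)
        assert summary.failure_detected

    def test_identical_curves_identical_summaries(self, geometry, protocol):
        params = synthdata.ConstitutiveParams(linear_modulus=10.0, uts=1.2,
                                              noise_sd=1.0, seed=11)
        t1 = synthdata.gen_trace(params, geometry, protocol)
        t2 = synthdata.gen_trace(params, geometry, protocol)
        s1, _ = mechanics.analyze_trace(t1, None, protocol, geometry.a0_min)
        s2, _ = mechanics.analyze_trace(t2, None, protocol, geometry.a0_min)
        assert s1 == s2

    def test_failure_before_first_window_is_an_error(self):
        curve = linear_curve(20.0)
        prof = tangent_modulus_profile(curve)
        with pytest.raises(ValueError, match="before the first full"):
            summarize(curve, prof, failure_index=2)

    def test_mtm_maximum_over_windows(self):
        curve = linear_curve(20.0, span=0.3)
        prof = tangent_modulus_profile(curve)
        summary = summarize(curve, prof, failure_index=len(curve) - 1,
                            failure_detected=False)
        assert all(summary.mtm >= w.slope - 1e-12 for w in prof)


class TestConventionProperties:
    def test_true_mtm_at_least_engineering_mtm(self, geometry, protocol):
        # for monotone-increasing curves with positive strain
        for seed in range(5):
            rng = np.random.default_rng(seed)
            E = rng.uniform(8, 30)
            params = synthdata.ConstitutiveParams(linear_modulus=E, uts=0.13 * E,
                                                  seed=seed)
            trace = synthdata.gen_trace(params, geometry, protocol)
            s_eng, _ = mechanics.analyze_trace(
                trace, None, protocol, geometry.a0_min, stress_convention="engineering"
            )
            s_true, _ = mechanics.analyze_trace(
                trace, None, protocol, geometry.a0_min, stress_convention="true"
            )
            assert s_true.mtm >= s_eng.mtm

    def test_mtm_window_starts_after_toe(self, geometry, protocol):
        # the maximum tangent modulus falls within the linear region
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            E = rng.uniform(8, 30)
            params = synthdata.ConstitutiveParams(
                linear_modulus=E, uts=0.14 * E, toe_strain=0.05, seed=seed
            )
            trace = synthdata.gen_trace(params, geometry, protocol)
            summary, _ = mechanics.analyze_trace(trace, None, protocol, geometry.a0_min)
            assert summary.mtm_window_start_strain >= 0.04
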