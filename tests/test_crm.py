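"""Reserve ground truth, window normalization, smoothing, trend, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgreserve import (
    CRMSeries,
    ansi_accuracy,
    build_standard_protocol,
    coefficient_of_determination,
    crm_ground_truth,
    evaluate_crm,
    generate_crm_predictions,
    ground_truth_series,
    median_errors,
    model_input_windows,
    normalize_window,
    smooth_predictions,
    trend_detection_time,
)
from ppgreserve.protocol import LBNPProtocol


class TestGroundTruth:
    def test_analytic_anchor_points(self):
        p = build_standard_protocol(-70)
        assert crm_ground_truth(p, 100.0) == 100.0  # baseline
        assert crm_ground_truth(p, 1799.0) == 0.0  # at HDD pressure
        # -35/-70 -> 50%: protocol with a -35 mmHg step
        p2 = LBNPProtocol(
            steps=((0.0, 300.0), (-35.0, 300.0)), hdd_pressure=-70.0
        )
        assert crm_ground_truth(p2, 450.0) == 50.0

    def test_monotone_in_pressure_magnitude(self):
        p = build_standard_protocol(-100)
        t = np.linspace(0, p.stop_time, 1000)
        gt = crm_ground_truth(p, t)
        assert np.all(np.diff(gt) <= 1e-12)
        assert gt[0] == 100.0 and gt[-1] == 0.0

    def test_clipped_when_pressure_exceeds_hdd(self):
        # decompensated mid-protocol: |LBNP| > |HDD| clips at 0
        p = LBNPProtocol(
            steps=((0.0, 300.0), (-60.0, 300.0)), hdd_pressure=-45.0
        )
        assert crm_ground_truth(p, 400.0) == 0.0

    def test_series_is_1hz_percent(self):
        p = build_standard_protocol(-15)
        s = ground_truth_series(p)
        assert len(s) == 601
        assert s.values[0] == 100.0
        assert s.values[-1] == 0.0


class TestNormalization:
    def test_affine_example(self):
        assert np.allclose(normalize_window([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    def test_idempotent_on_normalized(self):
        x = np.array([0.0, 0.25, 1.0])
        assert np.allclose(normalize_window(x), x)

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=50),
        st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, seed, a, b):
        x = np.random.default_rng(seed).standard_normal(50)
        assert np.allclose(
            normalize_window(a * x + b), normalize_window(x), atol=1e-9
        )

    def test_constant_window_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_window(np.full(500, 3.0))

    def test_model_windows_shape_and_degenerate_skip(self):
        x = np.concatenate([np.sin(np.arange(1000) * 0.1), np.zeros(500)])
        wins, starts = model_input_windows(x)
        assert wins.shape[1] == 500
        # every returned window attains 0 and 1 exactly
        assert np.allclose(wins.min(axis=1), 0.0)
        assert np.allclose(wins.max(axis=1), 1.0)
        # trailing constant window skipped
        assert len(starts) < (len(x) - 500) // 100 + 1


class TestSmoothing:
    def test_constant_series_unchanged(self):
        s = CRMSeries(np.full(100, 42.0))
        assert np.allclose(smooth_predictions(s).values, 42.0)

    def test_linear_ramp_interior_half_sample_offset(self):
        # the even 20-sample window spans [i-10, i+9]; on a linear series
        # its mean sits half a sample before i — the exact closed form
        s = CRMSeries(np.linspace(100.0, 0.0, 200))
        slope = s.values[1] - s.values[0]
        out = smooth_predictions(s)
        expected = s.values[10:-10] - 0.5 * slope
        assert np.max(np.abs(out.values[10:-10] - expected)) < 1e-9

    def test_impulse_response_matches_convolution(self):
        x = np.zeros(100)
        x[50] = 1.0
        out = smooth_predictions(CRMSeries(x)).values
        kernel = np.full(20, 1 / 20)
        # window [i-10, i+9] corresponds to full-convolution index i+9
        expected = np.convolve(x, kernel, mode="full")[9 : 9 + 100]
        assert np.allclose(out, expected, atol=1e-12)
        assert np.isclose(out.sum(), 1.0)

    def test_mean_preserving_interior(self):
        rng = np.random.default_rng(2)
        x = np.clip(50 + 10 * rng.standard_normal(400), 0, 100)
        out = smooth_predictions(CRMSeries(x)).values
        # windowed mean of interior equals raw mean of same span +/- edge effects
        assert abs(np.mean(out[10:-10]) - np.mean(x[10:-10])) < 0.5


class TestTrendDetection:
    def test_constant_series_never_detects(self):
        s = CRMSeries(np.full(1200, 80.0))
        assert trend_detection_time(s, stop_time=1200.0) == 0.0

    def test_linear_decline_5pct_per_min(self):
        # 100 -> 0 over 20 min: every 5-min window drops 25 >= 15
        s = CRMSeries(np.linspace(100.0, 0.0, 1201)[:1200])
        lead = trend_detection_time(s, stop_time=1200.0)
        assert lead == pytest.approx(15.0, abs=1e-9)

    def test_slow_decline_never_detects(self):
        # 2 %/min -> 10 points per window < 15
        s = CRMSeries(100.0 - 2.0 / 60.0 * np.arange(1200.0))
        assert trend_detection_time(s, stop_time=1200.0) == 0.0

    def test_threshold_boundary_closed_form(self):
        """Detection at the first window iff rate * 5 min >= 15 points."""
        for rate in (2.9, 3.0, 3.1):  # %/min
            vals = np.clip(100.0 - rate / 60.0 * np.arange(1800.0), 0, 100)
            lead = trend_detection_time(CRMSeries(vals), stop_time=1800.0)
            if rate >= 3.0:
                assert lead == pytest.approx((1800.0 - 300.0) / 60.0, abs=1e-6)
            else:
                assert lead == 0.0

    def test_endpoint_method_agrees_on_exact_lines(self):
        s = CRMSeries(np.linspace(100.0, 0.0, 1201)[:1200])
        a = trend_detection_time(s, 1200.0, method="ols")
        b = trend_detection_time(s, 1200.0, method="endpoint")
        assert a == pytest.approx(b, abs=1 / 60)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="5 min"):
            trend_detection_time(CRMSeries(np.full(200, 50.0)), stop_time=200.0)


class TestAgreementMetrics:
    def test_ansi_perfect_and_threshold_choice(self):
        ref = np.array([100.0, 100.0])
        assert ansi_accuracy(ref, ref) == 100.0
        # at ref=100 the 10% band (10 bpm) beats the 5 bpm band
        assert ansi_accuracy(np.array([109.0]), np.array([100.0])) == 100.0
        assert ansi_accuracy(np.array([111.0]), np.array([100.0])) == 0.0
        # at ref=40 the 5 bpm band is the wider one
        assert ansi_accuracy(np.array([44.9]), np.array([40.0])) == 100.0

    def test_ansi_matches_counting_oracle(self):
        rng = np.random.default_rng(31)
        ref = rng.uniform(60, 120, 1000)
        pred = ref + 4.0 * rng.standard_normal(1000)
        count = sum(
            1 for p, r in zip(pred, ref) if abs(p - r) <= max(5.0, 0.1 * r)
        )
        assert ansi_accuracy(pred, ref) == pytest.approx(100.0 * count / 1000)

    def test_median_errors_examples(self):
        ref = np.array([10.0, 20.0, 30.0])
        mde, mdae = median_errors(ref + 3.0, ref)
        assert (mde, mdae) == (3.0, 3.0)
        mde, mdae = median_errors(ref + np.array([-2.0, 0.0, 2.0]), ref)
        assert (mde, mdae) == (0.0, 2.0)

    def test_median_errors_sort_oracle(self):
        rng = np.random.default_rng(12)
        diff = rng.standard_normal(500)
        ref = np.zeros(500)
        mde, mdae = median_errors(diff, ref)
        s = np.sort(diff)
        assert mde == (s[249] + s[250]) / 2
        sa = np.sort(np.abs(diff))
        assert mdae == (sa[249] + sa[250]) / 2

    def test_r_squared_conventions(self):
        ref = np.linspace(0, 100, 200)
        assert coefficient_of_determination(ref, ref) == pytest.approx(1.0)
        # perfect negative linear relation: 1.0 under squared correlation
        assert coefficient_of_determination(-ref + 7, ref) == pytest.approx(1.0)
        # identity-line convention penalizes bias
        biased = ref + 10
        assert coefficient_of_determination(
            biased, ref, convention="identity"
        ) < coefficient_of_determination(biased, ref)

    def test_r_squared_algebraic_oracle(self):
        rng = np.random.default_rng(8)
        ref = rng.uniform(0, 100, 200)
        pred = 0.8 * ref + 5 + rng.standard_normal(200)
        cov = np.mean((pred - pred.mean()) * (ref - ref.mean()))
        expected = cov**2 / (np.var(pred) * np.var(ref))
        assert coefficient_of_determination(pred, ref) == pytest.approx(
            expected, abs=1e-12
        )

    def test_r_squared_zero_variance_absent(self):
        assert coefficient_of_determination(np.full(10, 5.0), np.arange(10.0)) is None


class TestEvaluateCRM:
    def test_recovers_injected_bias_exactly(self):
        gt = CRMSeries(np.full(900, 50.0), kind="ground_truth")
        pred = generate_crm_predictions(gt, bias=-20.0, noise_sd=0.0, seed=0)
        report = evaluate_crm(pred, gt)
        assert report.mde == -20.0
        assert report.mdae == 20.0

    def test_noise_mdae_converges_to_half_normal_median(self):
        gt = CRMSeries(np.full(1800, 50.0), kind="ground_truth")
        pred = generate_crm_predictions(gt, noise_sd=5.0, seed=7)
        report = evaluate_crm(pred, gt, smooth=False)
        assert abs(report.mdae - 3.372) / 3.372 < 0.10

    def test_trend_time_reported_when_stop_given(self):
        p = build_standard_protocol(-100)
        gt = ground_truth_series(p)
        pred = generate_crm_predictions(gt, seed=0)
        report = evaluate_crm(pred, gt, stop_time=p.stop_time)
        assert report.trend_time_min is not None
        assert report.trend_time_min > 0


def test_crm_series_validates_range():
    with pytest.raises(ValueError):
        CRMSeries(np.array([50.0, 120.0]))
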