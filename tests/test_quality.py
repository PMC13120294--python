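"""SNR decomposition, peak detection, and template-matching SQI."""

import numpy as np
import pytest

from ppgreserve import (
    Waveform,
    compute_window_sqi,
    detect_ppg_peaks,
    rolling_snr,
    rolling_sqi,
)
from ppgreserve.quality import SEGMENT_LENGTH

from conftest import clean_train


def two_tone(amp_low, amp_high, duration=60.0, fs=100.0):
    t = np.arange(int(duration * fs)) / fs
    x = amp_low * np.sin(2 * np.pi * 1.5 * t) + amp_high * np.sin(2 * np.pi * 15.0 * t)
    return Waveform(x, fs=fs)


class TestRollingSNR:
    def test_equal_amplitudes_near_zero_db(self):
        _, median = rolling_snr(two_tone(1.0, 1.0))
        assert abs(median) < 1.5

    def test_low_band_x10_shifts_plus_20db(self):
        _, base = rolling_snr(two_tone(1.0, 1.0))
        _, boosted = rolling_snr(two_tone(10.0, 1.0))
        assert abs((boosted - base) - 20.0) < 1.0

    def test_dc_offset_invariance(self):
        w = two_tone(1.0, 1.0)
        _, a = rolling_snr(w)
        _, b = rolling_snr(w.with_samples(w.samples + 123.0))
        assert abs(a - b) < 0.1

    def test_antisymmetric_under_band_swap(self):
        _, lo_heavy = rolling_snr(two_tone(10.0, 1.0))
        _, hi_heavy = rolling_snr(two_tone(1.0, 10.0))
        assert abs(lo_heavy + hi_heavy) < 1.0

    def test_window_count_bookkeeping(self):
        fs = 100.0
        for n_s in (5, 6, 12, 61):
            w = Waveform(np.sin(np.arange(int(n_s * fs)) * 0.3), fs=fs)
            windows, _ = rolling_snr(w)
            assert len(windows) == int((n_s * fs - 5 * fs) // fs) + 1

    def test_all_zero_input_gives_absent_median(self):
        windows, median = rolling_snr(Waveform(np.zeros(1000), fs=100.0))
        assert median is None
        assert all(not np.isfinite(qw.snr_db) for qw in windows)

    def test_too_short_recording(self):
        windows, median = rolling_snr(Waveform(np.zeros(400), fs=100.0))
        assert windows == [] and median is None


class TestPeakDetection:
    @pytest.mark.parametrize("hr,expected", [(60.0, 30), (120.0, 60)])
    def test_counts_and_timing_on_clean_trains(self, hr, expected):
        rec = clean_train(hr, 30.0)
        w = rec.ppg["custom"]
        peaks = detect_ppg_peaks(w)
        assert abs(len(peaks) - expected) <= 1
        peak_times = peaks / w.fs
        true = rec.true_beat_times
        for pt in peak_times:
            assert np.min(np.abs(true - pt)) < 0.030

    def test_all_zeros_yields_no_peaks(self):
        assert len(detect_ppg_peaks(Waveform(np.zeros(3000), fs=100.0))) == 0

    def test_negative_signal_yields_no_peaks(self):
        w = Waveform(-np.ones(3000), fs=100.0)
        assert len(detect_ppg_peaks(w)) == 0


def brute_force_sqi(x, peaks, fs, start, length):
    """Straight-line reimplementation: explicit loops over beats."""
    inside = [p for p in peaks if start <= p < start + length]
    if len(inside) >= 2:
        ibis = [
            (b - a) / fs for a, b in zip(inside[:-1], inside[1:])
        ]
        hr = 60.0 / (sum(ibis) / len(ibis))
        if not 40.0 <= hr <= 180.0 or max(ibis) > 3.0 or max(ibis) / min(ibis) > 2.2:
            return 0.0
    segs = []
    for j in range(1, len(inside) - 1):
        lo = (inside[j - 1] + inside[j]) // 2
        hi = (inside[j] + inside[j + 1]) // 2
        seg = x[lo:hi]
        if len(seg) < 2 or np.max(seg) - np.min(seg) == 0:
            continue
        grid = np.linspace(0, 1, SEGMENT_LENGTH)
        pos = np.linspace(0, 1, len(seg))
        segs.append(np.interp(grid, pos, seg))
    if len(segs) < 2:
        return 0.0
    template = np.mean(segs, axis=0)
    if np.max(template) - np.min(template) == 0:
        return 0.0
    total = 0.0
    for seg in segs:
        r = np.corrcoef(seg, template)[0, 1]
        total += min(max(r, 0.0), 1.0)
    return total / len(segs)


class TestSQI:
    def test_identical_beats_score_one(self, train_60):
        w = train_60.ppg["custom"]
        peaks = detect_ppg_peaks(w)
        sqi = compute_window_sqi(w, peaks)
        assert abs(sqi - 1.0) < 1e-6

    def test_white_noise_scores_zero_by_fallback(self):
        rng = np.random.default_rng(4)
        w = Waveform(rng.standard_normal(3000), fs=100.0)
        _, median = rolling_sqi(w)
        assert median == 0.0

    def test_alternating_morphologies_below_one_matches_oracle(self):
        # beats alternate: dicrotic bump amplitude 0 vs 0.5
        fs, n = 100.0, 3000
        t = np.arange(n) / fs
        x = np.zeros(n)
        for i, tb in enumerate(np.arange(0.5, 29.5, 1.0)):
            bump = 0.0 if i % 2 == 0 else 0.5
            x += np.exp(-0.5 * ((t - tb) / 0.08) ** 2)
            x += bump * np.exp(-0.5 * ((t - tb - 0.35) / 0.10) ** 2)
        w = Waveform(x, fs=fs)
        peaks = detect_ppg_peaks(w)
        sqi = compute_window_sqi(w, peaks)
        assert sqi < 1.0
        oracle = brute_force_sqi(w.samples, peaks, fs, 0, len(w))
        assert abs(sqi - oracle) < 1e-9

    def test_matches_brute_force_on_random_fixtures(self):
        """Oracle equivalence on 20 random noisy pulse fixtures."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            hr = rng.uniform(50, 150)
            noise = rng.uniform(0.0, 0.4)
            rec = clean_train(hr, 12.0, seed=int(rng.integers(1000)))
            x = rec.ppg["custom"].samples + noise * rng.standard_normal(1200)
            w = Waveform(x, fs=100.0)
            peaks = detect_ppg_peaks(w)
            mine = compute_window_sqi(w, peaks, start=100, length=1000)
            oracle = brute_force_sqi(x, peaks, 100.0, 100, 1000)
            assert abs(mine - oracle) < 1e-9

    def test_rolling_sqi_short_recording_absent(self):
        windows, median = rolling_sqi(Waveform(np.zeros(400), fs=100.0))
        assert windows == [] and median is None

    def test_window_outside_waveform_rejected(self):
        w = Waveform(np.zeros(1000), fs=100.0)
        with pytest.raises(ValueError, match="inside"):
            compute_window_sqi(w, np.array([]), start=600, length=500)

    def test_monotone_degradation_with_noise(self, train_60):
        """Adding stronger noise never raises the median SQI."""
        clean = train_60.ppg["custom"].samples
        rng = np.random.default_rng(23)
        noise = rng.standard_normal(len(clean))
        medians = []
        for sd in (0.0, 0.1, 0.3, 0.8, 2.0):
            w = Waveform(clean + sd * noise, fs=100.0)
            _, m = rolling_sqi(w)
            medians.append(m)
        assert all(b <= a + 1e-9 for a, b in zip(medians, medians[1:]))
        assert medians[0] > 0.99


def test_sqi_bounded_for_arbitrary_inputs():
    rng = np.random.default_rng(99)
    for _ in range(10):
        x = rng.standard_normal(800) * rng.uniform(0.1, 10)
        w = Waveform(x, fs=100.0)
        sqi = compute_window_sqi(w, detect_ppg_peaks(w))
        assert 0.0 <= sqi <= 1.0
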