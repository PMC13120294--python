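"""Rolling-window signal quality: SNR decomposition and beat-template SQI.

Two complementary quality measures are computed over 5 s windows advanced
1 s at a time:

* **SNR** — each window is AC-coupled with a 4th-order high-pass, then split
  at 5 Hz into a cardiac (low-pass) and a noise (high-pass) component with
  two 4th-order Butterworth filters; SNR_dB = 20*log10(RMS_signal/RMS_noise).
  The subject-level value is the median over windows.

* **SQI** — systolic peaks are detected with a two-moving-average event
  detector, beats are segmented around each peak, resampled to a common
  length and averaged into a template; the SQI is the mean Pearson
  correlation between individual beats and that template, on [0, 1]. Windows
  where no template can be formed (too few beats, degenerate morphology)
  score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .waveform import Waveform

__all__ = [
    "QualityWindow",
    "rolling_snr",
    "detect_ppg_peaks",
    "compute_window_sqi",
    "rolling_sqi",
]

logger = logging.getLogger(__name__)

#: Number of points each beat is resampled to before template correlation.
SEGMENT_LENGTH = 100

#: Beat-plausibility gates applied before template correlation: windows whose
#: detected rhythm falls outside a credible pulse (rate band in bpm, maximum
#: inter-beat interval in s, maximum IBI ratio) score 0 rather than the
#: chance correlation of non-cardiac events.
SQI_HR_GATE_BPM = (40.0, 180.0)
SQI_MAX_IBI_S = 3.0
SQI_MAX_IBI_RATIO = 2.2


@dataclass
class QualityWindow:
    """Per-window quality record with sample-index provenance."""

    start_index: int
    length: int
    snr_db: float | None = None
    sqi: float | None = None
    n_peaks: int = 0
    rms_signal: float = np.nan
    rms_noise: float = np.nan


def _window_starts(n_samples: int, fs: float, window_s: float, stride_s: float):
    length = int(round(window_s * fs))
    stride = int(round(stride_s * fs))
    if n_samples < length:
        return length, stride, []
    return length, stride, list(range(0, n_samples - length + 1, stride))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def rolling_snr(
    w: Waveform,
    window_s: float = 5.0,
    stride_s: float = 1.0,
    ac_cutoff_hz: float = 0.5,
    split_hz: float = 5.0,
) -> tuple[list[QualityWindow], float | None]:
    """Rolling-window SNR in dB plus the subject-level median.

    Within each window the signal is AC-coupled (4th-order Butterworth
    high-pass at ``ac_cutoff_hz``), then decomposed with 4th-order
    Butterworth low/high-pass filters at ``split_hz``: the low band is the
    cardiac pulsatile component, the high band broadband noise. Windows with
    exactly zero noise RMS record +inf and are excluded from the median;
    their count is logged.

    The decomposition filters are applied once over the full recording (the
    windows then slice the filtered components), so per-window RMS values are
    free of the zero-phase edge transients that repeated short-segment
    filtering would inject.

    Returns ``(windows, median_db)``; the median is ``None`` when no window
    yields a finite SNR (including recordings shorter than one window).
    """
    length, _, starts = _window_starts(len(w), w.fs, window_s, stride_s)
    sos_ac = signal.butter(4, ac_cutoff_hz, btype="highpass", fs=w.fs, output="sos")
    sos_lo = signal.butter(4, split_hz, btype="lowpass", fs=w.fs, output="sos")
    sos_hi = signal.butter(4, split_hz, btype="highpass", fs=w.fs, output="sos")

    windows: list[QualityWindow] = []
    n_inf = 0
    if starts:
        ac = signal.sosfiltfilt(sos_ac, w.samples)
        sig_full = signal.sosfiltfilt(sos_lo, ac)
        noise_full = signal.sosfiltfilt(sos_hi, ac)
    for start in starts:
        rs = _rms(sig_full[start : start + length])
        rn = _rms(noise_full[start : start + length])
        if rn == 0.0:
            snr = np.inf
            n_inf += 1
        else:
            snr = 20.0 * np.log10(rs / rn) if rs > 0 else -np.inf
        windows.append(
            QualityWindow(
                start_index=start, length=length, snr_db=snr,
                rms_signal=rs, rms_noise=rn,
            )
        )
    if n_inf:
        logger.info("%d windows had zero noise RMS; excluded from median", n_inf)
    finite = [qw.snr_db for qw in windows if np.isfinite(qw.snr_db)]
    median = float(np.median(finite)) if finite else None
    return windows, median


def detect_ppg_peaks(
    w: Waveform,
    peak_window_s: float = 0.111,
    beat_window_s: float = 0.667,
    offset_beta: float = 0.02,
) -> np.ndarray:
    """Detect systolic peaks with the two-moving-average event detector.

    The signal is clipped at zero and squared; a short moving average tracks
    systolic-peak duration and a long one beat duration. Regions where the
    short average exceeds the long average plus a small offset (proportional
    to the mean of the squared signal) become candidate systolic blocks;
    blocks narrower than the short window are rejected and each surviving
    block contributes the index of its maximum.

    Returns an array of peak sample indices (possibly empty).
    """
    x = np.asarray(w.samples, dtype=float)
    if len(x) == 0:
        return np.array([], dtype=int)
    clipped = np.where(x > 0, x, 0.0)
    squared = clipped * clipped
    if not np.any(squared > 0):
        return np.array([], dtype=int)

    w1 = max(1, int(round(peak_window_s * w.fs)))
    w2 = max(w1 + 1, int(round(beat_window_s * w.fs)))
    ma_peak = np.convolve(squared, np.ones(w1) / w1, mode="same")
    ma_beat = np.convolve(squared, np.ones(w2) / w2, mode="same")
    alpha = offset_beta * float(np.mean(squared))
    interest = ma_peak > (ma_beat + alpha)

    peaks = []
    edges = np.flatnonzero(np.diff(interest.astype(np.int8)))
    block_starts = edges[interest[edges + 1]] + 1 if len(edges) else np.array([], int)
    # handle block open at index 0
    if interest[0]:
        block_starts = np.concatenate([[0], block_starts])
    block_ends = edges[~interest[edges + 1]] + 1 if len(edges) else np.array([], int)
    if interest[-1]:
        block_ends = np.concatenate([block_ends, [len(interest)]])
    for s, e in zip(block_starts, block_ends):
        if e - s >= w1:
            peaks.append(s + int(np.argmax(x[s:e])))
    return np.asarray(peaks, dtype=int)


def _beat_segments(
    x: np.ndarray, peaks: np.ndarray
) -> tuple[list[np.ndarray], int]:
    """Midpoint-to-midpoint beat segments resampled to a common length.

    A peak contributes a segment only when it has both neighbours (the
    segment spans from the midpoint to the previous peak to the midpoint to
    the next). Zero-variance segments are skipped; their count is returned.
    """
    segments: list[np.ndarray] = []
    n_skipped = 0
    grid = np.linspace(0.0, 1.0, SEGMENT_LENGTH)
    for i in range(1, len(peaks) - 1):
        lo = (peaks[i - 1] + peaks[i]) // 2
        hi = (peaks[i] + peaks[i + 1]) // 2
        seg = x[lo:hi]
        if len(seg) < 2 or np.ptp(seg) == 0:
            n_skipped += 1
            continue
        pos = np.linspace(0.0, 1.0, len(seg))
        segments.append(np.interp(grid, pos, seg))
    return segments, n_skipped


def compute_window_sqi(
    w: Waveform, peaks: np.ndarray, start: int = 0, length: int | None = None
) -> float:
    """Template-matching SQI for one window, on [0, 1].

    Beats whose peaks fall inside ``[start, start+length)`` are segmented,
    resampled to a common length, and averaged into a reference template;
    the SQI is the mean over beats of the Pearson correlation between beat
    and template, with negative correlations clipped to 0. Windows fall back
    to 0 when the detected rhythm is implausible as a pulse (rate outside
    40-180 bpm, an inter-beat gap over 3 s, or a max/min IBI ratio above
    2.2), when fewer than two usable beats remain, or when the template is
    degenerate.
    """
    if length is None:
        length = len(w) - start
    if start < 0 or start + length > len(w):
        raise ValueError("window not fully inside waveform")
    x = np.asarray(w.samples, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    in_win = peaks[(peaks >= start) & (peaks < start + length)]
    if len(in_win) >= 2:
        ibis = np.diff(in_win) / w.fs
        hr = 60.0 / np.mean(ibis)
        if (
            not SQI_HR_GATE_BPM[0] <= hr <= SQI_HR_GATE_BPM[1]
            or np.max(ibis) > SQI_MAX_IBI_S
            or np.max(ibis) / np.min(ibis) > SQI_MAX_IBI_RATIO
        ):
            return 0.0
    segments, n_skipped = _beat_segments(x, in_win)
    if n_skipped:
        logger.debug("skipped %d zero-variance beat segments", n_skipped)
    if len(segments) < 2:
        return 0.0
    template = np.mean(segments, axis=0)
    if np.ptp(template) == 0:
        return 0.0
    corrs = []
    for seg in segments:
        r = np.corrcoef(seg, template)[0, 1]
        corrs.append(min(max(r, 0.0), 1.0))
    return float(np.mean(corrs))


def rolling_sqi(
    w: Waveform, window_s: float = 5.0, stride_s: float = 1.0
) -> tuple[list[QualityWindow], float | None]:
    """Rolling-window SQI plus the subject-level median.

    Peaks are re-detected on each window's own samples, so a window's score
    reflects only its local morphology. Recordings shorter than one window
    yield an empty list and an absent median.
    """
    length, _, starts = _window_starts(len(w), w.fs, window_s, stride_s)
    windows: list[QualityWindow] = []
    for start in starts:
        seg_wave = Waveform(
            samples=w.samples[start : start + length], fs=w.fs,
            t0=w.t0 + start / w.fs, channel=w.channel,
        )
        peaks = detect_ppg_peaks(seg_wave)
        sqi = compute_window_sqi(seg_wave, peaks)
        windows.append(
            QualityWindow(
                start_index=start, length=length, sqi=sqi, n_peaks=len(peaks)
            )
        )
    vals = [qw.sqi for qw in windows if qw.sqi is not None]
    median = float(np.median(vals)) if vals else None
    return windows, median
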