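"""Compensatory reserve: ground truth, model-input windowing, evaluation.

The compensatory reserve measurement (CRM) expresses how much physiological
capacity to compensate for central blood loss remains, from 100% (full
reserve) to 0% (onset of hemodynamic decompensation). Under a graded LBNP
protocol the ground truth is

    CRM_GT(t) = 100 * (1 - |LBNP(t)| / |LBNP_HDD|),

piecewise constant on pressure steps and clipped to [0, 100], where
LBNP_HDD is the pressure at which the subject decompensates.

Prediction series (1 Hz) are post-processed with a 20-sample centered moving
average and scored with R^2, median error (bias), median absolute error,
ANSI/AAMI-style accuracy, and a trend-detection lead time: the number of
minutes before protocol stop at which a sliding 5-minute window first shows
a CRM decline of at least 15 percentage points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .protocol import LBNPProtocol

__all__ = [
    "CRMSeries",
    "EvalReport",
    "crm_ground_truth",
    "ground_truth_series",
    "normalize_window",
    "model_input_windows",
    "smooth_predictions",
    "trend_detection_time",
    "ansi_accuracy",
    "median_errors",
    "coefficient_of_determination",
    "evaluate_crm",
]

logger = logging.getLogger(__name__)

#: Model-input window contract: 5 s of 100 Hz samples.
MODEL_WINDOW_SAMPLES = 500
MODEL_FS_HZ = 100.0


@dataclass(frozen=True)
class CRMSeries:
    """Reserve values in percent at a uniform 1 Hz cadence."""

    values: np.ndarray
    t0: float = 0.0
    kind: str = "prediction"  # ground_truth | prediction | smoothed_prediction

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if np.any(vals < -1e-9) or np.any(vals > 100 + 1e-9):
            raise ValueError("CRM values must lie in [0, 100] percent")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values), dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def crm_ground_truth(protocol: LBNPProtocol, t) -> np.ndarray | float:
    """Ground-truth reserve (percent) at time(s) ``t``.

    100% at atmospheric pressure, 0% at the decompensation pressure, linear
    in pressure magnitude in between and clipped to [0, 100]; piecewise
    constant on protocol steps. ``t`` outside ``[0, stop_time]`` is rejected.
    """
    pressure = protocol.pressure_at(t)
    frac = 1.0 - np.abs(pressure) / abs(protocol.hdd_pressure)
    out = 100.0 * np.clip(frac, 0.0, 1.0)
    return float(out) if np.isscalar(out) or np.ndim(out) == 0 else out


def ground_truth_series(protocol: LBNPProtocol) -> CRMSeries:
    """Ground truth sampled at 1 Hz over ``[0, stop_time]``."""
    t = np.arange(0.0, np.floor(protocol.stop_time) + 0.5)
    return CRMSeries(values=crm_ground_truth(protocol, t), kind="ground_truth")


def normalize_window(window: np.ndarray) -> np.ndarray:
    """Min-max scale one model-input window to [0, 1].

    Each sample maps to (x_i - min)/(max - min), so the output attains 0 and
    1 exactly. A constant window is degenerate (the scale is undefined) and
    is rejected; callers skip and count such windows.
    """
    x = np.asarray(window, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise ValueError("degenerate constant window cannot be normalized")
    return (x - lo) / (hi - lo)


def model_input_windows(
    samples: np.ndarray, fs: float = MODEL_FS_HZ, window_s: float = 5.0,
    stride_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized 5 s windows at 1 s stride, as a pluggable predictor expects.

    Returns ``(windows, start_times)`` where each row of ``windows`` is a
    min-max-normalized 500-sample window. Degenerate constant windows are
    skipped with a logged count.
    """
    length = int(round(window_s * fs))
    stride = int(round(stride_s * fs))
    rows, starts = [], []
    n_degenerate = 0
    for start in range(0, len(samples) - length + 1, stride):
        win = samples[start : start + length]
        try:
            rows.append(normalize_window(win))
        except ValueError:
            n_degenerate += 1
            continue
        starts.append(start / fs)
    if n_degenerate:
        logger.info("skipped %d degenerate constant windows", n_degenerate)
    if not rows:
        return np.empty((0, length)), np.array([])
    return np.vstack(rows), np.asarray(starts)


def smooth_predictions(pred: CRMSeries, window: int = 20) -> CRMSeries:
    """Centered moving average over ``window`` samples (20 s at 1 Hz).

    For the default even window each smoothed value covers the 10 preceding
    samples, the sample itself, and the 9 following — the closest an even
    window comes to a symmetric 10 s/10 s span. Edges use shrinking windows
    (mean over the available samples), so a constant series is unchanged
    everywhere.
    """
    x = np.asarray(pred.values, dtype=float)
    n = len(x)
    before = window // 2  # samples before self
    after = window - before - 1  # samples after self
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        lo = max(0, i - before)
        hi = min(n, i + after + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return CRMSeries(values=out, t0=pred.t0, kind="smoothed_prediction")


def trend_detection_time(
    pred: CRMSeries,
    stop_time: float,
    drop_percent: float = 15.0,
    window_min: float = 5.0,
    stride_s: float = 1.0,
    method: str = "ols",
) -> float:
    """Lead time (minutes before stop) of the first significant decline.

    A 5-minute window slides at 1 s stride; it "drops" when its fitted
    linear trend falls by at least ``drop_percent`` CRM points across the
    nominal window span. Detection time is the end of the earliest such
    window; the returned lead time is ``(stop_time - detection)/60``,
    so larger values mean earlier warning. Returns 0.0 when no window ever
    meets the threshold.

    ``method='ols'`` (default) estimates the trend with an ordinary
    least-squares slope; ``method='endpoint'`` uses the raw last-minus-first
    difference.
    """
    span_s = window_min * 60.0
    length = int(round(span_s))  # samples at 1 Hz
    x = np.asarray(pred.values, dtype=float)
    if len(x) < length:
        raise ValueError("series shorter than the trend window (5 min)")
    stride = int(round(stride_s))
    t_rel = np.arange(length, dtype=float)
    t_centered = t_rel - t_rel.mean()
    denom = float(np.sum(t_centered**2))
    for start in range(0, len(x) - length + 1, stride):
        win = x[start : start + length]
        if method == "ols":
            slope = float(np.sum(t_centered * (win - win.mean()))) / denom
            drop = -slope * span_s
        elif method == "endpoint":
            drop = float(win[0] - win[-1])
        else:
            raise ValueError(f"unknown trend method {method!r}")
        if drop >= drop_percent:
            detection_time = pred.t0 + start + span_s
            return max(0.0, (stop_time - detection_time) / 60.0)
    return 0.0


def ansi_accuracy(pred: np.ndarray, ref: np.ndarray) -> float:
    """Percent of pairs within +/-5 bpm or +/-10% of reference (greater wins).

    Implements the ANSI/AAMI EC13-style heart-rate accuracy criterion: each
    pair's tolerance is ``max(5, 0.10*ref)`` and a pair counts as accurate
    when ``|pred - ref|`` is within it.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(pred) == 0 or len(pred) != len(ref):
        raise ValueError("need at least one prediction/reference pair")
    threshold = np.maximum(5.0, 0.10 * np.abs(ref))
    return 100.0 * float(np.mean(np.abs(pred - ref) <= threshold))


def median_errors(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Median signed error (bias) and median absolute error.

    MdE = median(pred - ref) characterizes systematic bias; MdAE =
    median(|pred - ref|) quantifies accuracy independent of bias direction.
    """
    diff = np.asarray(pred, dtype=float) - np.asarray(ref, dtype=float)
    if len(diff) == 0:
        raise ValueError("need at least one pair")
    return float(np.median(diff)), float(np.median(np.abs(diff)))


def coefficient_of_determination(
    pred: np.ndarray, ref: np.ndarray, convention: str = "correlation"
) -> float | None:
    """R^2 between prediction and reference.

    ``convention='correlation'`` (default) returns the squared sample
    correlation — scatterplot agreement irrespective of scale and offset.
    ``convention='identity'`` returns 1 - SS_res/SS_tot about the identity
    line, which penalizes bias. Returns None (with a logged reason) when
    either side has zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs for R^2")
    if np.var(pred) == 0 or np.var(ref) == 0:
        logger.info("R^2 undefined: zero variance on one side")
        return None
    if convention == "correlation":
        r = np.corrcoef(pred, ref)[0, 1]
        return float(r * r)
    if convention == "identity":
        ss_res = float(np.sum((pred - ref) ** 2))
        ss_tot = float(np.sum((ref - ref.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown R^2 convention {convention!r}")


@dataclass
class EvalReport:
    """Agreement metrics for one prediction/reference pairing."""

    r_squared: float | None
    mde: float
    mdae: float
    ansi_accuracy: float
    trend_time_min: float | None = None
    n_pairs: int = 0


def evaluate_crm(
    pred: CRMSeries,
    gt: CRMSeries,
    stop_time: float | None = None,
    smooth: bool = True,
    trend_method: str = "ols",
) -> EvalReport:
    """Score a CRM prediction series against ground truth.

    Predictions are smoothed (20 s centered mean) before scoring and trend
    detection unless ``smooth=False``. Series are truncated to their common
    length from a shared time origin. Trend time is computed only when
    ``stop_time`` is given and the series covers at least 5 minutes.
    """
    series = smooth_predictions(pred) if smooth else pred
    n = min(len(series), len(gt))
    p, g = series.values[:n], gt.values[:n]
    mde, mdae = median_errors(p, g)
    report = EvalReport(
        r_squared=coefficient_of_determination(p, g),
        mde=mde,
        mdae=mdae,
        ansi_accuracy=ansi_accuracy(p, g),
        n_pairs=n,
    )
    if stop_time is not None and n >= 300:
        report.trend_time_min = trend_detection_time(
            CRMSeries(p, t0=series.t0, kind=series.kind), stop_time,
            method=trend_method,
        )
    return report
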