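"""Beat-to-beat heart rate from pulse peaks, plausibility screening, pairing.

Heart rate is the reciprocal of the inter-beat interval, 60/IBI bpm, placed
at each inter-beat midpoint and linearly interpolated onto a uniform 1 Hz
grid so that predicted and reference series can be paired sample-for-sample.
Only the reference (ECG-stand-in) series is screened for physiological
plausibility; the PPG-derived series is taken as-is, so detector failures
show up honestly in the accuracy metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BeatSeries", "hr_from_peaks", "screen_reference_hr", "align_pairs"]

logger = logging.getLogger(__name__)

#: Clinical plausibility band for the reference heart rate, bpm (inclusive).
HR_PLAUSIBLE_BPM = (30.0, 200.0)


@dataclass
class BeatSeries:
    """Detected pulse-peak times plus the heart-rate series derived from them."""

    peak_times: np.ndarray  # seconds, strictly increasing
    hr: pd.Series  # bpm indexed by time (s), uniform 1 Hz
    source: str = ""


def hr_from_peaks(peak_times: np.ndarray, grid_hz: float = 1.0) -> pd.Series:
    """Instantaneous heart rate (bpm) on a uniform grid from peak times.

    Each inter-beat interval contributes 60/IBI bpm at its midpoint; the
    midpoint series is linearly interpolated onto a uniform ``grid_hz`` grid
    spanning the midpoints. Fewer than two peaks yield an empty series.
    """
    t = np.asarray(peak_times, dtype=float)
    if len(t) < 2:
        return pd.Series(dtype=float, name="hr_bpm")
    if np.any(np.diff(t) <= 0):
        raise ValueError("peak times must be strictly increasing")
    ibi = np.diff(t)
    mid = t[:-1] + ibi / 2
    hr = 60.0 / ibi
    step = 1.0 / grid_hz
    start = np.ceil(mid[0] / step) * step
    stop = np.floor(mid[-1] / step) * step
    if stop < start:
        return pd.Series(dtype=float, name="hr_bpm")
    grid = np.arange(start, stop + step / 2, step)
    vals = np.interp(grid, mid, hr)
    return pd.Series(vals, index=np.round(grid, 9), name="hr_bpm")


def screen_reference_hr(
    hr: pd.Series, bounds: tuple[float, float] = HR_PLAUSIBLE_BPM
) -> pd.Series:
    """Drop reference samples outside the plausibility band (inclusive bounds).

    Values exactly at the band edges are retained; the number of removed
    samples is logged. Idempotent.
    """
    lo, hi = bounds
    keep = (hr >= lo) & (hr <= hi)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("screened %d implausible reference HR samples", n_removed)
    return hr[keep]


def align_pairs(
    pred: pd.Series, ref: pd.Series, ref_offset_s: float = 0.0
) -> pd.DataFrame:
    """Pair predicted and reference series on their common 1 Hz grid.

    ``ref_offset_s`` shifts the reference timestamps by a known clock offset
    before pairing. Grid points missing on either side are dropped and the
    drop counts logged. Raises when the series do not overlap in time.

    Returns a DataFrame with columns ``pred`` and ``ref`` indexed by time (s).
    """
    ref = ref.copy()
    ref.index = np.round(np.asarray(ref.index, dtype=float) - ref_offset_s, 9)
    common = pred.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError("predicted and reference series do not overlap in time")
    pairs = pd.DataFrame({"pred": pred.reindex(common), "ref": ref.reindex(common)})
    n_before = len(pairs)
    pairs = pairs.dropna()
    if len(pairs) < n_before:
        logger.info("dropped %d incomplete pairs", n_before - len(pairs))
    logger.debug(
        "paired %d samples (pred-only %d, ref-only %d)",
        len(pairs), len(pred) - len(common), len(ref) - len(common),
    )
    return pairs
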