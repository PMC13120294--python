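"""Lower-body negative pressure (LBNP) protocol model.

An LBNP run applies progressively stronger negative chamber pressure to a
supine subject to pull blood into the lower body, reversibly emulating
hemorrhage. The standard ladder is a 5-minute atmospheric baseline, then
-15 mmHg steps every 5 minutes down to -60 mmHg, then -10 mmHg steps until
presyncope (hemodynamic decompensation) or -100 mmHg. The pressure at which
the subject decompensates (LBNP_HDD) anchors the compensatory-reserve ground
truth: reserve is 100% at 0 mmHg and 0% at the decompensation pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LBNPProtocol", "build_standard_protocol", "STANDARD_LADDER"]

#: Pressure ladder of the standard protocol (mmHg), baseline first.
STANDARD_LADDER: tuple[int, ...] = (0, -15, -30, -45, -60, -70, -80, -90, -100)

#: Duration of every step in the standard protocol (seconds).
STEP_DURATION_S: float = 300.0


@dataclass(frozen=True)
class LBNPProtocol:
    """Ordered pressure steps plus the decompensation pressure.

    Parameters
    ----------
    steps
        Ordered ``(pressure_mmHg, duration_s)`` pairs. The first step must be
        the 0 mmHg baseline and pressure magnitudes must be non-decreasing.
    hdd_pressure
        Pressure (mmHg, negative) at hemodynamic decompensation; the
        denominator of the reserve ground truth. The subject may decompensate
        mid-step, so its magnitude is not required to exceed the last applied
        pressure.
    stop_time
        Time (s) at which the run ends — presyncope or protocol completion.
    """

    steps: tuple[tuple[float, float], ...]
    hdd_pressure: float
    stop_time: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("protocol needs at least one step")
        if self.steps[0][0] != 0:
            raise ValueError("first step must be the 0 mmHg baseline")
        mags = [abs(p) for p, _ in self.steps]
        if any(b < a for a, b in zip(mags, mags[1:])):
            raise ValueError("pressure magnitudes must be non-decreasing")
        if any(d <= 0 for _, d in self.steps):
            raise ValueError("step durations must be positive")
        if any(p > 0 for p, _ in self.steps):
            raise ValueError("step pressures must be non-positive (mmHg)")
        if self.hdd_pressure == 0:
            raise ValueError("hdd_pressure must be nonzero")
        if self.stop_time is None:
            object.__setattr__(self, "stop_time", self.total_duration)
        if self.stop_time > self.total_duration + 1e-9:
            raise ValueError("stop_time exceeds total protocol duration")

    @property
    def total_duration(self) -> float:
        """Summed duration of all steps (s)."""
        return float(sum(d for _, d in self.steps))

    @property
    def step_starts(self) -> np.ndarray:
        """Start time (s) of each step."""
        return np.concatenate([[0.0], np.cumsum([d for _, d in self.steps])[:-1]])

    def pressure_at(self, t) -> np.ndarray | float:
        """Applied pressure LBNP(t) in mmHg; piecewise constant on steps.

        Accepts a scalar or array of times in ``[0, stop_time]``.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0) or np.any(t_arr > self.stop_time + 1e-9):
            raise ValueError(
                f"time outside recording span [0, {self.stop_time}] s"
            )
        edges = np.cumsum([d for _, d in self.steps])
        idx = np.searchsorted(edges, t_arr, side="right")
        idx = np.minimum(idx, len(self.steps) - 1)
        pressures = np.array([p for p, _ in self.steps])
        out = pressures[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def build_standard_protocol(
    hdd_pressure: float,
    completed: bool = True,
    presyncope_fraction: float = 1.0,
) -> LBNPProtocol:
    """Build the standard graded LBNP ladder truncated at decompensation.

    Steps run 0, -15, -30, -45, -60 mmHg in -15 mmHg increments, then
    -70, -80, -90, -100 mmHg in -10 mmHg increments, each lasting 5 minutes.

    Parameters
    ----------
    hdd_pressure
        Pressure (mmHg) of the step at which the subject decompensates;
        must be one of the ladder levels (excluding baseline).
    completed
        If True the subject finishes the final step; otherwise the run stops
        ``presyncope_fraction`` of the way into it.
    presyncope_fraction
        Fraction of the final step completed when ``completed`` is False,
        in (0, 1].
    """
    valid = STANDARD_LADDER[1:]
    if hdd_pressure not in valid:
        raise ValueError(
            f"hdd_pressure {hdd_pressure} not on the ladder; valid steps: "
            f"{list(valid)}"
        )
    if not 0 < presyncope_fraction <= 1:
        raise ValueError("presyncope_fraction must be in (0, 1]")
    idx = STANDARD_LADDER.index(hdd_pressure)
    steps = tuple((float(p), STEP_DURATION_S) for p in STANDARD_LADDER[: idx + 1])
    total = STEP_DURATION_S * (idx + 1)
    if completed:
        stop = total
    else:
        stop = total - STEP_DURATION_S + presyncope_fraction * STEP_DURATION_S
    return LBNPProtocol(steps=steps, hdd_pressure=float(hdd_pressure), stop_time=stop)
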