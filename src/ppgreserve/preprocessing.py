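"""Resampling and band-pass filtering strategies applied before analysis.

Three filter families are supported, mirroring the conditions compared in
wearable-PPG validation work:

* a 4th-order Butterworth band-pass (0.5-8 Hz), zero-phase;
* a 4th-order Chebyshev type II band-pass (0.5-8 Hz, 40 dB stopband
  attenuation), zero-phase;
* a linear-phase FIR band-pass applied by direct convolution with a declared
  group delay and constant edge replication. Proprietary device coefficients
  are not redistributable, so :func:`standin_fir_spec` ships a windowed-sinc
  stand-in with the identical application contract.

Zero-phase IIR filtering runs the designed filter forward then backward
(``sosfiltfilt``), so the effective magnitude response is the squared design
response and the net phase is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .waveform import Waveform

__all__ = [
    "FilterSpec",
    "decimate_by_selection",
    "apply_bandpass",
    "apply_fir_custom",
    "apply_filter",
    "standin_fir_spec",
    "butterworth_spec",
    "chebyshev2_spec",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filtering condition.

    ``passband`` is the (low, high) critical-frequency pair in Hz. For
    ``chebyshev2`` the conventional design semantics apply: these are the
    frequencies at which attenuation first reaches ``stopband_attenuation``
    (``band_interpretation='critical'``, the default). Set
    ``band_interpretation='passband'`` to instead treat them as 3 dB
    passband edges, solved for numerically.
    """

    family: str  # butterworth | chebyshev2 | fir_custom
    order: int = 4
    passband: tuple[float, float] = (0.5, 8.0)
    stopband_attenuation: float = 40.0
    fir_coefficients: np.ndarray | None = None
    fir_delay: int = 0
    zero_phase: bool = True
    band_interpretation: str = "critical"  # critical | passband

    def __post_init__(self) -> None:
        if self.family not in ("butterworth", "chebyshev2", "fir_custom"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        low, high = self.passband
        if not 0 < low < high:
            raise ValueError("passband must satisfy 0 < low < high")
        if self.family == "chebyshev2" and self.stopband_attenuation <= 0:
            raise ValueError("stopband attenuation must be positive (dB)")
        if self.fir_coefficients is not None:
            object.__setattr__(
                self, "fir_coefficients", np.asarray(self.fir_coefficients, float)
            )


def butterworth_spec(low: float = 0.5, high: float = 8.0, order: int = 4) -> FilterSpec:
    """4th-order Butterworth band-pass, zero-phase."""
    return FilterSpec(family="butterworth", order=order, passband=(low, high))


def chebyshev2_spec(
    low: float = 0.5,
    high: float = 8.0,
    order: int = 4,
    attenuation_db: float = 40.0,
    band_interpretation: str = "critical",
) -> FilterSpec:
    """4th-order Chebyshev type II band-pass with 40 dB stopband attenuation."""
    return FilterSpec(
        family="chebyshev2",
        order=order,
        passband=(low, high),
        stopband_attenuation=attenuation_db,
        band_interpretation=band_interpretation,
    )


def decimate_by_selection(w: Waveform, factor: int) -> Waveform:
    """Downsample by keeping every ``factor``-th sample, no anti-alias filter.

    This reproduces plain decimation-by-selection (e.g. 1 kHz -> 100 Hz by
    taking every 10th value). Content above the new Nyquist frequency will
    alias; a warning is logged because this is a deliberate departure from
    textbook decimation.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValueError("decimation factor must be an integer >= 1")
    factor = int(factor)
    if len(w) < factor:
        raise ValueError("waveform shorter than decimation factor")
    if factor == 1:
        return w
    logger.warning(
        "decimating by selection (factor %d) without anti-alias filtering; "
        "content above %.1f Hz will alias",
        factor,
        w.fs / (2 * factor),
    )
    return Waveform(
        samples=w.samples[::factor], fs=w.fs / factor, t0=w.t0, channel=w.channel
    )


def _design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    low, high = spec.passband
    nyq = fs / 2
    for edge, name in ((low, "low"), (high, "high")):
        if edge >= nyq:
            raise ValueError(
                f"{name} passband edge {edge} Hz is at or above Nyquist ({nyq} Hz)"
            )
    if spec.family == "butterworth":
        return signal.butter(spec.order, [low, high], btype="bandpass", fs=fs, output="sos")
    if spec.family == "chebyshev2":
        if spec.band_interpretation == "critical":
            wn = (low, high)
        elif spec.band_interpretation == "passband":
            wn = _cheby2_edges_for_passband(spec, fs)
        else:
            raise ValueError(
                f"unknown band_interpretation {spec.band_interpretation!r}"
            )
        return signal.cheby2(
            spec.order, spec.stopband_attenuation, wn, btype="bandpass", fs=fs, output="sos"
        )
    raise ValueError(f"{spec.family} is not an IIR band-pass family")


def _cheby2_edges_for_passband(spec: FilterSpec, fs: float) -> tuple[float, float]:
    """Solve for cheby2 critical frequencies so the stated band is the 3 dB band."""
    low, high = spec.passband
    target = 10 ** (-3 / 20)  # single-pass 3 dB points

    def gain_err(wn):
        a, b = wn
        if not 0 < a < b < fs / 2:
            return [1e3, 1e3]
        sos = signal.cheby2(
            spec.order, spec.stopband_attenuation, [a, b], btype="bandpass", fs=fs,
            output="sos",
        )
        _, h = signal.sosfreqz(sos, worN=np.array([low, high]), fs=fs)
        return [abs(h[0]) - target, abs(h[1]) - target]

    sol = optimize.fsolve(gain_err, x0=[low * 0.6, high * 1.4], full_output=False)
    a, b = float(sol[0]), float(sol[1])
    if not 0 < a < b < fs / 2:
        raise ValueError("could not solve cheby2 passband-edge design")
    return a, b


def apply_bandpass(w: Waveform, spec: FilterSpec) -> Waveform:
    """Apply an IIR band-pass, zero-phase by default.

    Forward-backward application (``sosfiltfilt``) cancels phase so pulse
    landmarks are not shifted; the cascaded magnitude response is the square
    of the single-pass design. Output has the same length and sampling rate;
    DC is fully rejected.
    """
    if spec.family not in ("butterworth", "chebyshev2"):
        raise ValueError("apply_bandpass expects a butterworth or chebyshev2 spec")
    sos = _design_sos(spec, w.fs)
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, w.samples)
    else:
        out = signal.sosfilt(sos, w.samples)
    return w.with_samples(out)


def apply_fir_custom(w: Waveform, spec: FilterSpec) -> Waveform:
    """Convolve with an FIR kernel, compensating its declared group delay.

    The input is boundary-padded by constant edge replication, convolved with
    the coefficient vector, and the output shifted back by ``fir_delay``
    samples so output sample k aligns with input sample k. Length and
    sampling rate are preserved.
    """
    if spec.family != "fir_custom":
        raise ValueError("apply_fir_custom expects a fir_custom spec")
    if spec.fir_coefficients is None:
        raise ValueError(
            "fir_custom spec has no coefficients; load device coefficients or "
            "use standin_fir_spec() to synthesize a stand-in kernel"
        )
    h = spec.fir_coefficients
    n = len(h)
    pad = max(n - 1, 1)
    padded = np.pad(w.samples, pad, mode="edge")
    full = np.convolve(padded, h, mode="full")
    start = pad + spec.fir_delay
    out = full[start : start + len(w.samples)]
    return w.with_samples(out)


def apply_filter(w: Waveform, spec: FilterSpec | None) -> Waveform:
    """Dispatch on filter family; ``None`` returns the waveform unchanged (raw)."""
    if spec is None:
        return w
    if spec.family == "fir_custom":
        return apply_fir_custom(w, spec)
    return apply_bandpass(w, spec)


def standin_fir_spec(
    fs: float = 100.0, n_taps: int = 1001, low: float = 0.5, high: float = 8.0
) -> FilterSpec:
    """Synthetic linear-phase FIR band-pass standing in for device coefficients.

    A Hamming-windowed sinc design (default 1001 taps at 100 Hz, group delay
    500 samples) with the same application mechanics — convolution with a
    fixed declared delay and edge replication — as the proprietary kernel it
    replaces.
    """
    if n_taps % 2 == 0:
        raise ValueError("n_taps must be odd for an integer group delay")
    taps = signal.firwin(n_taps, [low, high], pass_zero=False, fs=fs)
    taps = taps - taps.mean()  # force an exact zero at DC
    return FilterSpec(
        family="fir_custom",
        order=n_taps - 1,
        passband=(low, high),
        fir_coefficients=taps,
        fir_delay=(n_taps - 1) // 2,
    )
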