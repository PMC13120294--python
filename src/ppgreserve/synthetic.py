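"""Seedable multi-site PPG simulator for progressive central hypovolemia.

Generates aligned recordings — PPG per sensor site, a reference heart-rate
series standing in for ECG-derived HR, ground-truth compensatory reserve,
and surrogate CRM predictions — with the statistical structure the analysis
pipeline assumes, so every downstream stage is testable without access to
human LBNP data.

The physiological model is deliberately simple: beats follow an
inhomogeneous point process whose rate rises linearly as reserve falls
(tachycardic compensation), each beat contributes a two-bump pulse template
(systolic peak plus dicrotic bump) whose amplitude shrinks as reserve falls,
and site-specific artifacts — baseline wander, DC offset, broadband noise,
motion bursts, coupling dropouts — are added on top. Site presets reproduce
the qualitative contrast seen across wearable placements: a finger-like
site is clean; a triceps-like site has strong pulsatility buried under
heavy baseline wander and DC offset (so raw-signal quality fails but
band-passed quality is high); a clavicle-like site has weak pulsatility
dominated by broadband noise.

One root seed is split into independent child streams per signal component,
so toggling one noise source does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crm import CRMSeries, crm_ground_truth, ground_truth_series
from .protocol import LBNPProtocol
from .waveform import Waveform

__all__ = [
    "SiteProfile",
    "SubjectRecording",
    "SITE_PROFILES",
    "generate_recording",
    "generate_multisite",
    "generate_crm_predictions",
]

#: Default heart-rate drift law: HR(t) = HR_BASE + HR_GAIN * (1 - reserve).
HR_BASE_BPM = 70.0
HR_GAIN_BPM = 50.0

#: Relative standard deviation of inter-beat-interval jitter.
IBI_JITTER_SD = 0.01


@dataclass(frozen=True)
class SiteProfile:
    """Noise and coupling characteristics of one sensor placement."""

    name: str
    pulse_amplitude: float = 1.0  # a.u., systolic peak height at full reserve
    amplitude_decay: float = 0.5  # fraction of baseline amplitude left at 0% reserve
    wander_amplitude: float = 0.0  # a.u., sub-0.5 Hz baseline drift
    dc_offset: float = 0.0  # a.u.
    noise_sd: float = 0.0  # a.u., broadband white noise
    motion_burst_rate: float = 0.0  # events per minute
    coupling_dropout_prob: float = 0.0  # per 5 s block

    def __post_init__(self) -> None:
        if self.pulse_amplitude <= 0:
            raise ValueError("pulse_amplitude must be positive")
        if not 0 <= self.amplitude_decay <= 1:
            raise ValueError("amplitude_decay must be in [0, 1]")
        for name in ("wander_amplitude", "noise_sd", "motion_burst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.coupling_dropout_prob <= 1:
            raise ValueError("coupling_dropout_prob must be a probability")


#: Site presets reproducing the qualitative cross-placement contrast.
SITE_PROFILES: dict[str, SiteProfile] = {
    "finger": SiteProfile(
        name="finger", pulse_amplitude=1.0, wander_amplitude=0.05,
        dc_offset=0.0, noise_sd=0.01,
    ),
    "triceps": SiteProfile(
        name="triceps", pulse_amplitude=1.0, wander_amplitude=50.0,
        dc_offset=15.0, noise_sd=0.02, motion_burst_rate=0.5,
    ),
    "clavicle": SiteProfile(
        name="clavicle", pulse_amplitude=0.12, wander_amplitude=0.8,
        dc_offset=3.0, noise_sd=0.5, motion_burst_rate=2.0,
        coupling_dropout_prob=0.05,
    ),
}


@dataclass
class SubjectRecording:
    """Aligned streams for one simulated subject.

    All streams share the time origin t=0 and cover ``[0, stop_time]``.
    """

    ppg: dict[str, Waveform]
    true_beat_times: np.ndarray
    reference_hr: pd.Series  # bpm at 1 Hz, ECG stand-in
    crm_gt: CRMSeries
    protocol: LBNPProtocol
    seed: int


def _hr_at(protocol: LBNPProtocol, t, hr_base: float, hr_gain: float):
    reserve = np.asarray(crm_ground_truth(protocol, t)) / 100.0
    return hr_base + hr_gain * (1.0 - reserve)


def _draw_beat_times(
    protocol: LBNPProtocol, rng: np.random.Generator,
    hr_base: float, hr_gain: float, ibi_jitter_sd: float,
) -> np.ndarray:
    """Inhomogeneous beat point process with multiplicative IBI jitter."""
    times = []
    t = 0.05  # first beat shortly after recording start
    while t < protocol.stop_time:
        times.append(t)
        hr = float(_hr_at(protocol, min(t, protocol.stop_time), hr_base, hr_gain))
        ibi = 60.0 / hr
        if ibi_jitter_sd > 0:
            ibi *= max(0.2, 1.0 + ibi_jitter_sd * rng.standard_normal())
        else:
            rng.standard_normal()  # keep stream position stable when jitter off
        t += ibi
    return np.asarray(times)


def _asymmetric_gaussian(t: np.ndarray, center: float, s_rise: float, s_fall: float):
    sigma = np.where(t < center, s_rise, s_fall)
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _render_pulses(
    beat_times: np.ndarray, protocol: LBNPProtocol, profile: SiteProfile,
    fs: float, n: int,
) -> np.ndarray:
    """Sum of per-beat two-bump templates scaled by remaining reserve."""
    out = np.zeros(n)
    t_axis = np.arange(n) / fs
    ibis = np.diff(beat_times)
    for i, tb in enumerate(beat_times):
        ibi = ibis[i] if i < len(ibis) else (ibis[-1] if len(ibis) else 0.85)
        reserve = crm_ground_truth(protocol, min(tb, protocol.stop_time)) / 100.0
        amp = profile.pulse_amplitude * (
            profile.amplitude_decay + (1 - profile.amplitude_decay) * reserve
        )
        lo = max(0, int((tb - 0.5 * ibi) * fs))
        hi = min(n, int((tb + 0.9 * ibi) * fs) + 1)
        if hi <= lo:
            continue
        tt = t_axis[lo:hi]
        systolic = _asymmetric_gaussian(tt, tb, 0.08 * ibi, 0.14 * ibi)
        dicrotic = _asymmetric_gaussian(
            tt, tb + 0.35 * ibi, 0.10 * ibi, 0.10 * ibi
        )
        out[lo:hi] += amp * (systolic + 0.25 * dicrotic)
    return out


def _render_wander(n: int, fs: float, amplitude: float, rng: np.random.Generator):
    """Sub-0.5 Hz baseline drift as a random sum of slow sinusoids."""
    t = np.arange(n) / fs
    freqs = rng.uniform(0.05, 0.4, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    weights = rng.uniform(0.5, 1.0, size=4)
    drift = np.zeros(n)
    for f, p, a in zip(freqs, phases, weights):
        drift += a * np.sin(2 * np.pi * f * t + p)
    if amplitude == 0:
        return np.zeros(n)
    return amplitude * drift / np.sum(weights)


def _render_motion(
    n: int, fs: float, rate_per_min: float, scale: float, rng: np.random.Generator
):
    """Laplace-amplitude transients of 0.5-2 s emulating motion artifacts."""
    out = np.zeros(n)
    duration_min = n / fs / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    t_axis = np.arange(n) / fs
    for _ in range(n_events):
        t_e = rng.uniform(0, n / fs)
        dur = rng.uniform(0.5, 2.0)
        amp = scale * rng.laplace(0.0, 1.0)
        tau = dur / 4.0
        lo = max(0, int((t_e - dur) * fs))
        hi = min(n, int((t_e + dur) * fs) + 1)
        out[lo:hi] += amp * np.exp(-np.abs(t_axis[lo:hi] - t_e) / tau)
    return out


def _dropout_mask(
    n: int, fs: float, prob: float, rng: np.random.Generator, block_s: float = 5.0
):
    """1/0 mask zeroing the pulsatile component in randomly lost blocks."""
    mask = np.ones(n)
    block = int(block_s * fs)
    for start in range(0, n, block):
        if rng.uniform() < prob:
            mask[start : start + block] = 0.0
    return mask


def generate_recording(
    protocol: LBNPProtocol,
    profile: SiteProfile,
    fs: float = 100.0,
    seed: int = 0,
    hr_base: float = HR_BASE_BPM,
    hr_gain: float = HR_GAIN_BPM,
    ibi_jitter_sd: float = IBI_JITTER_SD,
) -> SubjectRecording:
    """Simulate one subject at one sensor site.

    Identical arguments (including seed) give bit-identical output. The
    reference heart-rate series is the configured rate law HR(t) =
    ``hr_base + hr_gain * (1 - reserve)`` sampled at 1 Hz — an idealized
    ECG-derived ground truth.
    """
    return generate_multisite(
        protocol, [profile], fs=fs, seed=seed,
        hr_base=hr_base, hr_gain=hr_gain, ibi_jitter_sd=ibi_jitter_sd,
    )


def generate_multisite(
    protocol: LBNPProtocol,
    profiles: list[SiteProfile],
    fs: float = 100.0,
    seed: int = 0,
    hr_base: float = HR_BASE_BPM,
    hr_gain: float = HR_GAIN_BPM,
    ibi_jitter_sd: float = IBI_JITTER_SD,
) -> SubjectRecording:
    """Simulate one subject at several sites sharing one cardiac stream.

    Beat times are drawn once (one heart); each site renders its own pulse
    train and adds profile-specific artifacts from independent child RNG
    streams spawned from the root seed.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    root = np.random.SeedSequence(seed)
    beat_ss, *site_ss = root.spawn(1 + len(profiles))
    beat_rng = np.random.Generator(np.random.PCG64(beat_ss))
    beat_times = _draw_beat_times(protocol, beat_rng, hr_base, hr_gain, ibi_jitter_sd)

    n = int(round(protocol.stop_time * fs))
    ppg: dict[str, Waveform] = {}
    for profile, ss in zip(profiles, site_ss):
        wander_ss, noise_ss, motion_ss, dropout_ss = ss.spawn(4)
        pulses = _render_pulses(beat_times, protocol, profile, fs, n)
        mask = _dropout_mask(
            n, fs, profile.coupling_dropout_prob,
            np.random.Generator(np.random.PCG64(dropout_ss)),
        )
        wander = _render_wander(
            n, fs, profile.wander_amplitude,
            np.random.Generator(np.random.PCG64(wander_ss)),
        )
        noise_rng = np.random.Generator(np.random.PCG64(noise_ss))
        noise = (
            profile.noise_sd * noise_rng.standard_normal(n)
            if profile.noise_sd > 0 else np.zeros(n)
        )
        motion = _render_motion(
            n, fs, profile.motion_burst_rate, 5.0 * profile.pulse_amplitude,
            np.random.Generator(np.random.PCG64(motion_ss)),
        )
        samples = pulses * mask + wander + profile.dc_offset + noise + motion
        ppg[profile.name] = Waveform(samples=samples, fs=fs, channel=profile.name)

    t_ref = np.arange(0.0, np.floor(protocol.stop_time) + 0.5)
    reference_hr = pd.Series(
        _hr_at(protocol, t_ref, hr_base, hr_gain), index=t_ref, name="hr_bpm"
    )
    return SubjectRecording(
        ppg=ppg,
        true_beat_times=beat_times,
        reference_hr=reference_hr,
        crm_gt=ground_truth_series(protocol),
        protocol=protocol,
        seed=seed,
    )


def generate_crm_predictions(
    crm_gt: CRMSeries,
    bias: float = 0.0,
    noise_sd: float = 0.0,
    lag: float = 0.0,
    seed: int = 0,
) -> CRMSeries:
    """Surrogate reserve predictions: lagged, biased, noisy ground truth.

    ``prediction(t) = clip(gt(t - lag) + bias + N(0, noise_sd), 0, 100)``,
    at 1 Hz. Stands in for a pluggable waveform-based predictor so the
    evaluation stage can be exercised with known injected error structure.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    gt = np.asarray(crm_gt.values, dtype=float)
    lag_samples = int(round(lag))
    if lag_samples > 0:
        lagged = np.concatenate([np.full(lag_samples, gt[0]), gt[:-lag_samples]])
    elif lag_samples < 0:
        k = -lag_samples
        lagged = np.concatenate([gt[k:], np.full(k, gt[-1])])
    else:
        lagged = gt
    noise = noise_sd * rng.standard_normal(len(gt)) if noise_sd > 0 else 0.0
    values = np.clip(lagged + bias + noise, 0.0, 100.0)
    return CRMSeries(values=values, t0=crm_gt.t0, kind="prediction")
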