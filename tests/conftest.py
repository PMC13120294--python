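"""Shared fixtures: protocols, noise-free pulse trains, site recordings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from ppgreserve import (
    LBNPProtocol,
    SiteProfile,
    build_standard_protocol,
    generate_recording,
)


def constant_protocol(duration_s: float = 30.0) -> LBNPProtocol:
    """Baseline-only protocol: reserve stays at 100%, HR stays at hr_base."""
    return LBNPProtocol(
        steps=((0.0, duration_s),), hdd_pressure=-70.0, stop_time=duration_s
    )


def clean_profile(name: str = "custom", amplitude: float = 1.0) -> SiteProfile:
    """All noise sources off: pure pulse train."""
    return SiteProfile(name=name, pulse_amplitude=amplitude, amplitude_decay=1.0)


def clean_train(hr_bpm: float, duration_s: float, fs: float = 100.0, seed: int = 0):
    """Noise-free constant-rate recording (no IBI jitter)."""
    return generate_recording(
        constant_protocol(duration_s),
        clean_profile(),
        fs=fs,
        seed=seed,
        hr_base=hr_bpm,
        hr_gain=0.0,
        ibi_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def train_60():
    return clean_train(60.0, 30.0)


@pytest.fixture(scope="session")
def train_120():
    return clean_train(120.0, 30.0)


@pytest.fixture(scope="session")
def ramp_recording():
    """Noise-free finger-like recording over a short graded protocol."""
    return generate_recording(
        build_standard_protocol(-30.0),
        clean_profile(),
        seed=3,
        ibi_jitter_sd=0.0,
    )
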