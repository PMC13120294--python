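"""Uniformly sampled waveform container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Waveform"]


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled single-channel amplitude series.

    Attributes
    ----------
    samples
        Amplitudes in arbitrary units.
    fs
        Sampling rate in Hz (> 0).
    t0
        Time of the first sample, seconds.
    channel
        Free-form label (e.g. site name plus filter condition).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(len(self.samples)) / self.fs

    def with_samples(self, samples: np.ndarray, channel: str | None = None) -> "Waveform":
        """Copy with new samples (same fs/t0), optionally relabelled."""
        return replace(
            self, samples=samples, channel=self.channel if channel is None else channel
        )
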