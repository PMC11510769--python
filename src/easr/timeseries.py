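"""The 1-D sampled-signal container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """A single-channel sampled signal.

    Parameters
    ----------
    samples
        Amplitude values in microvolts (µV). Stored as a float64 array.
    fs
        Sampling rate in Hz. Must be positive.
    label
        Free-text channel name (e.g. ``"Fp1"``).
    """

    samples: np.ndarray
    fs: float
    label: str = "EEG"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ConfigurationError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 2:
            raise ConfigurationError("a TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ConfigurationError("samples must all be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Signal length in seconds (= n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        """Return a copy of this series carrying new sample values."""
        return TimeSeries(samples=np.asarray(samples, dtype=np.float64),
                          fs=self.fs, label=self.label)

    def __len__(self) -> int:
        return self.n_samples
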