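"""Pre-processing chain for raw single-channel EEG.

Zero-centering, a 0.5–100 Hz band-pass, and a 50 Hz power-line notch — the
standard conditioning applied before embedding. No detrending is performed.

Filters are a 4th-order Butterworth band-pass and a second-order IIR notch
(quality factor 30), both run forward–backward (``filtfilt``) so the chain is
zero-phase: blink peaks used later by the amplitude detector are not shifted.
Reflect padding at the signal ends suppresses edge transients.
"""

from __future__ import annotations

from scipy import signal as sps

from .exceptions import ConfigurationError
from .timeseries import TimeSeries

__all__ = ["zero_center", "bandpass", "notch", "preprocess"]


def zero_center(ts: TimeSeries) -> TimeSeries:
    """Subtract the mean amplitude (zero-centered normalization).

    No variance rescaling is applied; only the DC offset is removed.
    """
    return ts.with_samples(ts.samples - ts.samples.mean())


def bandpass(ts: TimeSeries, lo: float = 0.5, hi: float = 100.0, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz."""
    nyq = ts.fs / 2.0
    if not 0 < lo < hi:
        raise ConfigurationError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ConfigurationError(f"hi={hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    return ts.with_samples(sps.sosfiltfilt(sos, ts.samples))


def notch(ts: TimeSeries, f0: float = 50.0, quality: float = 30.0) -> TimeSeries:
    """Zero-phase IIR notch removing the ``f0`` Hz power-line component."""
    nyq = ts.fs / 2.0
    if not 0 < f0 < nyq:
        raise ConfigurationError(f"notch frequency {f0} Hz must lie in (0, {nyq})")
    b, a = sps.iirnotch(f0, quality, fs=ts.fs)
    return ts.with_samples(sps.filtfilt(b, a, ts.samples))


def preprocess(
    ts: TimeSeries,
    band_lo: float = 0.5,
    band_hi: float = 100.0,
    notch_freq: float | None = 50.0,
) -> TimeSeries:
    """Full conditioning chain: zero-center → band-pass → notch.

    Set ``notch_freq`` to ``None`` to skip the line-noise notch (e.g. for
    synthetic signals that carry none). Signal length is preserved exactly.
    """
    out = zero_center(ts)
    out = bandpass(out, band_lo, band_hi)
    if notch_freq is not None:
        out = notch(out, notch_freq)
    return out
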