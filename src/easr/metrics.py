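"""Evaluation suite: RRMSE, correlation, band-power ratios, blink counting.

The blink detector is an amplitude-threshold rule: a sample is a blink apex
if it is a local maximum exceeding

    threshold = constant × mean(|x|)          (constant = 6 by default)

and at least 250 ms away from any larger detected peak. The mean of the
*absolute* amplitude is used: on zero-centered EEG the raw mean is ~0 and
would make the threshold degenerate. Because the threshold scales with the
signal, detection is invariant to positive rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .exceptions import ConfigurationError, DimensionError, NumericDomainError
from .semisim import rms
from .timeseries import TimeSeries

__all__ = [
    "DEFAULT_BANDS",
    "BlinkEvents",
    "MetricsReport",
    "rrmse",
    "pearson_cc",
    "band_power_ratios",
    "detect_blinks",
    "percent_reduction",
    "evaluate",
]

#: Canonical EEG bands (Hz), tiling 0.5–100 Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}


@dataclass(frozen=True)
class BlinkEvents:
    """Detected blink peaks and the detector settings that produced them."""

    peak_indices: np.ndarray
    threshold: float
    min_separation: float
    constant: float
    fs: float

    @property
    def count(self) -> int:
        return int(self.peak_indices.size)

    @property
    def peak_times(self) -> np.ndarray:
        """Peak locations in seconds."""
        return self.peak_indices / self.fs


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of the evaluation numbers for one cleaned signal."""

    rrmse_percent: float | None
    cc: float | None
    band_power_ratios: dict[str, float]
    blinks_before: int
    blinks_after: int
    percent_reduction: float | None

    def to_dict(self) -> dict:
        return {
            "rrmse_percent": self.rrmse_percent,
            "cc": self.cc,
            "band_power_ratios": dict(self.band_power_ratios),
            "blinks_before": self.blinks_before,
            "blinks_after": self.blinks_after,
            "percent_reduction": self.percent_reduction,
        }


def _aligned(a: TimeSeries, b: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
    if a.n_samples != b.n_samples:
        raise DimensionError(
            f"signals differ in length ({a.n_samples} vs {b.n_samples})"
        )
    return a.samples, b.samples


def rrmse(test: TimeSeries, reference: TimeSeries) -> float:
    """Relative root mean square error, 100·RMS(test − reference)/RMS(reference), in %."""
    x, ref = _aligned(test, reference)
    denom = rms(ref)
    if denom == 0:
        raise NumericDomainError("reference signal has zero RMS")
    return float(100.0 * rms(x - ref) / denom)


def pearson_cc(a: TimeSeries, b: TimeSeries) -> float:
    """Pearson correlation coefficient between two equal-length signals."""
    x, y = _aligned(a, b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NumericDomainError("correlation undefined for a constant signal")
    return float(stats.pearsonr(x, y).statistic)


def band_power_ratios(
    ts: TimeSeries, bands: dict[str, tuple[float, float]] | None = None
) -> dict[str, float]:
    """Fraction of spectral power in each named band.

    Power comes from an averaged periodogram (Welch: 2-s Hann segments, 50%
    overlap); each band sums the PSD over bins with lo ≤ f < hi, and the
    denominator is the power over the union of the bands, so ratios over
    bands that tile the spectrum sum to one.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    hi_edge = max(hi for _, hi in bands.values())
    if hi_edge > ts.fs / 2:
        raise ConfigurationError(
            f"band edge {hi_edge} Hz exceeds Nyquist ({ts.fs / 2} Hz)"
        )
    nperseg = min(int(round(2 * ts.fs)), ts.n_samples)
    freqs, psd = sps.welch(ts.samples, fs=ts.fs, nperseg=nperseg)
    lo_edge = min(lo for lo, _ in bands.values())
    total = psd[(freqs >= lo_edge) & (freqs < hi_edge)].sum()
    if total == 0:
        raise NumericDomainError("signal has no power in the analysis range")
    return {
        name: float(psd[(freqs >= lo) & (freqs < hi)].sum() / total)
        for name, (lo, hi) in bands.items()
    }


def detect_blinks(
    ts: TimeSeries,
    constant: float = 6.0,
    min_sep: float = 0.25,
    absolute: bool = False,
) -> BlinkEvents:
    """Count eye-blinks by amplitude thresholding.

    Peaks are local maxima above ``constant × mean(|x|)``; peaks closer than
    ``min_sep`` seconds are merged keeping the larger. ``absolute=True``
    detects on |x| instead of x (for inverted montages).
    """
    x = np.abs(ts.samples) if absolute else ts.samples
    threshold = float(constant * np.mean(np.abs(ts.samples)))
    distance = max(1, int(round(min_sep * ts.fs)))
    peaks, _ = sps.find_peaks(x, height=threshold, distance=distance)
    return BlinkEvents(
        peak_indices=peaks,
        threshold=threshold,
        min_separation=min_sep,
        constant=constant,
        fs=ts.fs,
    )


def percent_reduction(before: int, after: int) -> float:
    """Percentage reduction in blink count, 100·(before − after)/before.

    Defined as 0 when nothing was there to remove (before = 0 = after).
    """
    if before < 0 or after < 0:
        raise NumericDomainError("blink counts cannot be negative")
    if before == 0:
        if after == 0:
            return 0.0
        raise NumericDomainError(
            f"no blinks before but {after} after; reduction undefined"
        )
    return float(100.0 * (before - after) / before)


def evaluate(
    cleaned: TimeSeries,
    original: TimeSeries,
    reference: TimeSeries | None = None,
    constant: float = 6.0,
    min_sep: float = 0.25,
) -> MetricsReport:
    """Full report for a cleaned signal.

    RRMSE and CC are computed against ``reference`` (the ground truth) when
    one is available, else against ``original``; blink counts compare the
    original with the cleaned signal; band ratios describe the cleaned signal.
    """
    ref = reference if reference is not None else original
    before = detect_blinks(original, constant=constant, min_sep=min_sep).count
    after = detect_blinks(cleaned, constant=constant, min_sep=min_sep).count
    try:
        reduction: float | None = percent_reduction(before, after)
    except NumericDomainError:
        reduction = None
    return MetricsReport(
        rrmse_percent=rrmse(cleaned, ref),
        cc=pearson_cc(cleaned, ref),
        band_power_ratios=band_power_ratios(cleaned),
        blinks_before=before,
        blinks_after=after,
        percent_reduction=reduction,
    )
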