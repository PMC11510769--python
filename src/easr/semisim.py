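"""Semi-simulated blink-contaminated EEG with known ground truth.

The benchmark construction: two distinct 10-s clean EEG segments are
replicated and concatenated into a 1-minute ground-truth signal; two blink
templates are zero-padded to 10 s; each 10-s segment then receives one blink,

    z = s + α·m,

where the mixing coefficient α sets the segment's signal-to-noise ratio
through SNR = 10·log10(RMS(s) / RMS(α·m)), drawn uniformly from [−7, 2] dB.
The (clean segment × blink template) pairings cycle through their four
combinations in lexicographic order, so the six segments cover every pairing.

The clean segments here are fully synthetic stand-ins for recorded EEG:
band-limited (0.5–100 Hz) 1/f-weighted Gaussian noise with a 10 Hz alpha
component, 10 µV standard deviation. The blink template is a smooth
raised-cosine-squared deflection (~0.3 s wide, seeded asymmetry between rise
and fall) inside a 2-s segment, peaking at 400 µV before mixing — at the low
end of the SNR range the mixed blink reaches the several-hundred-µV scale of
real prefrontal blinks, whose power sits below 20 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .exceptions import ConfigurationError, DimensionError, NumericDomainError
from .timeseries import TimeSeries

__all__ = [
    "SemiSimSpec",
    "SemiSimDataset",
    "synth_clean_eeg",
    "synth_blink",
    "pad_blink",
    "rms",
    "mixing_coefficient",
    "build_semisimulated",
]


@dataclass(frozen=True)
class SemiSimSpec:
    """Parameters of the semi-simulated dataset builder."""

    fs: float = 500.0
    clean_segment_s: float = 10.0
    blink_s: float = 2.0
    n_segments: int = 6
    snr_db_range: tuple[float, float] = (-7.0, 2.0)
    blink_amplitude: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_db_range[0] > self.snr_db_range[1]:
            raise ConfigurationError(f"bad SNR range {self.snr_db_range}")
        if self.blink_s >= self.clean_segment_s:
            raise ConfigurationError("blink segment must be shorter than clean segment")
        if self.n_segments < 1 or self.fs <= 0:
            raise ConfigurationError("need n_segments >= 1 and fs > 0")


@dataclass(frozen=True)
class SemiSimDataset:
    """Ground truth + contaminated signal + the blink bookkeeping."""

    ground_truth: TimeSeries
    contaminated: TimeSeries
    blink_onsets: np.ndarray      # first contaminated sample of each blink
    blink_peaks: np.ndarray       # sample index of each blink apex
    alphas: np.ndarray            # per-segment mixing coefficients
    snrs_db: np.ndarray           # per-segment SNR actually used
    spec: SemiSimSpec


def synth_clean_eeg(duration: float, fs: float, seed: int) -> TimeSeries:
    """Synthetic artifact-free background EEG.

    Gaussian noise spectrally shaped to 1/f power inside 0.5–100 Hz with a
    1% amplitude broadband floor outside the band (a measurement-noise floor
    that also keeps delay-embedded covariances full rank), plus a 10 Hz
    alpha rhythm. Output is rescaled to a 10 µV standard deviation.
    """
    if duration <= 0:
        raise ConfigurationError(f"duration must be > 0, got {duration}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    white = rng.standard_normal(n)
    spectrum = sfft.rfft(white)
    freqs = sfft.rfftfreq(n, d=1.0 / fs)
    # Per-band power budget of awake eyes-open prefrontal EEG (fractions of
    # total power). The across-band decay of the budget gives the spectrum
    # its 1/f-like trend; within a band the density is flat.
    band_budget = {
        (0.5, 4.0): 0.23,
        (4.0, 8.0): 0.15,
        (8.0, 13.0): 0.05,   # the other half of alpha comes from the 10 Hz line
        (13.0, 30.0): 0.41,
        (30.0, 100.0): 0.11,
    }
    weight = np.zeros_like(freqs)
    for (lo, hi), frac in band_budget.items():
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            continue
        weight[sel] = np.sqrt(frac / sel.sum())
    in_band = weight > 0
    # 1% amplitude broadband floor: a measurement-noise floor that also keeps
    # delay-embedded covariances full rank
    weight[~in_band] = 0.01 * weight[in_band].mean()
    weight[freqs == 0] = 0.0
    background = sfft.irfft(spectrum * weight, n=n)
    background /= background.std()
    t = np.arange(n) / fs
    # 10 Hz alpha line carrying ~5% of total power (unit-variance background)
    alpha = np.sqrt(2 * 0.05 / 0.95) * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
    x = background + alpha
    x = x / x.std() * 10.0
    return TimeSeries(samples=x, fs=fs, label="synthetic-clean")


def synth_blink(
    fs: float,
    duration: float = 2.0,
    amplitude: float = 400.0,
    seed: int = 0,
    width: float = 0.3,
) -> TimeSeries:
    """Synthetic eye-blink template inside a ``duration``-s segment.

    A raised-cosine-squared bump of total width ~``width`` seconds, centred
    in the segment, peaking exactly at ``amplitude`` µV, with a seeded ±10%
    asymmetry between rise and fall. Spectral power is concentrated well
    below 20 Hz.
    """
    if amplitude <= 0:
        raise ConfigurationError(f"amplitude must be > 0, got {amplitude}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    peak_idx = n // 2
    rise = max(2, int(round(0.5 * width * fs * (1 + 0.1 * rng.uniform(-1, 1)))))
    fall = max(2, int(round(0.5 * width * fs * (1 + 0.1 * rng.uniform(-1, 1)))))
    x = np.zeros(n)
    u_rise = np.arange(rise + 1) / rise            # 0..1, hits 1 at the apex
    x[peak_idx - rise : peak_idx + 1] = np.sin(np.pi * u_rise / 2) ** 4
    u_fall = 1.0 - np.arange(fall + 1) / fall
    x[peak_idx : peak_idx + fall + 1] = np.sin(np.pi * u_fall / 2) ** 4
    x[peak_idx] = 1.0
    return TimeSeries(samples=x * amplitude, fs=fs, label="synthetic-blink")


def pad_blink(blink: TimeSeries, target: float = 10.0, position: float = 0.5) -> TimeSeries:
    """Zero-pad a blink segment to ``target`` seconds.

    ``position`` places the blink fractionally within the padded segment:
    0 = flush at the start, 0.5 = centred, 1 = flush at the end.
    """
    n_target = int(round(target * blink.fs))
    n_blink = blink.n_samples
    if n_blink > n_target:
        raise DimensionError(
            f"blink ({n_blink} samples) longer than target ({n_target})"
        )
    start = int(round(position * (n_target - n_blink)))
    out = np.zeros(n_target)
    out[start : start + n_blink] = blink.samples
    return TimeSeries(samples=out, fs=blink.fs, label=blink.label)


def rms(x) -> float:
    """Root mean square, sqrt(mean(x²))."""
    x = np.asarray(x.samples if isinstance(x, TimeSeries) else x, dtype=np.float64)
    if x.size == 0:
        raise NumericDomainError("RMS of an empty sequence is undefined")
    return float(np.sqrt(np.mean(x**2)))


def mixing_coefficient(s, m, snr_db: float) -> float:
    """Mixing coefficient α realizing SNR = 10·log10(RMS(s)/RMS(α·m)).

    Note the convention: the SNR is 10·log10 of an RMS (amplitude) ratio,
    so α = RMS(s) / (RMS(m)·10^(SNR/10)).
    """
    rms_m = rms(m)
    if rms_m == 0:
        raise NumericDomainError("blink segment has zero RMS; cannot mix")
    return rms(s) / (rms_m * 10.0 ** (snr_db / 10.0))


def build_semisimulated(spec: SemiSimSpec | None = None) -> SemiSimDataset:
    """Assemble the full semi-simulated dataset from a spec (default: 60 s)."""
    spec = spec or SemiSimSpec()
    seeds = np.random.SeedSequence(spec.seed).generate_state(5)
    cleans = [
        synth_clean_eeg(spec.clean_segment_s, spec.fs, int(seeds[0])),
        synth_clean_eeg(spec.clean_segment_s, spec.fs, int(seeds[1])),
    ]
    raw_blinks = [
        synth_blink(spec.fs, spec.blink_s, spec.blink_amplitude, int(seeds[2])),
        synth_blink(spec.fs, spec.blink_s, spec.blink_amplitude, int(seeds[3])),
    ]
    rng = np.random.default_rng(int(seeds[4]))
    snrs = rng.uniform(spec.snr_db_range[0], spec.snr_db_range[1], spec.n_segments)
    # one blink per segment at a random position well inside the segment —
    # real blinks fall anywhere, and a fixed position would be artificially
    # phase-locked to the cleaning windows
    positions = rng.uniform(0.15, 0.85, spec.n_segments)

    # the four (clean, blink) pairings in lexicographic order, cycled
    pairings = [(0, 0), (0, 1), (1, 0), (1, 1)]
    seg_len = cleans[0].n_samples
    gt_parts, noise_parts = [], []
    alphas = np.empty(spec.n_segments)
    onsets = np.empty(spec.n_segments, dtype=np.int64)
    peaks = np.empty(spec.n_segments, dtype=np.int64)
    for i in range(spec.n_segments):
        ci, bi = pairings[i % 4]
        s = cleans[ci]
        m = pad_blink(raw_blinks[bi], target=spec.clean_segment_s,
                      position=positions[i])
        alpha = mixing_coefficient(s, m, snrs[i])
        alphas[i] = alpha
        gt_parts.append(s.samples)
        noise_parts.append(alpha * m.samples)
        nz = np.nonzero(m.samples)[0]
        onsets[i] = i * seg_len + nz[0]
        peaks[i] = i * seg_len + int(np.argmax(m.samples))
    ground_truth = np.concatenate(gt_parts)
    contaminated = ground_truth + np.concatenate(noise_parts)
    return SemiSimDataset(
        ground_truth=TimeSeries(ground_truth, spec.fs, "ground-truth"),
        contaminated=TimeSeries(contaminated, spec.fs, "contaminated"),
        blink_onsets=onsets,
        blink_peaks=peaks,
        alphas=alphas,
        snrs_db=snrs,
        spec=spec,
    )
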