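# Methods

## The model

E-ASR treats a single EEG channel as a dynamical system observed through a
delay map. The unit-lag Hankel embedding `X[i, j] = x(i + j)` (M rows,
K = N − M + 1 columns) turns temporal structure into "spatial" structure:
each row is a lagged copy of the signal, and the covariance of the rows is
the signal's autocovariance up to lag M − 1. A high-variance transient such
as an eye-blink occupies a low-dimensional subspace of this pseudo-channel
space (the Hankel patch of a smooth bump is effectively rank ≈ 3), which is
exactly the situation artifact subspace reconstruction is built for. After
cleaning, anti-diagonal averaging maps the matrix back to a signal; for a
matrix that is no longer exactly Hankel this is the least-squares-closest
signal, and the composition with the embedding is the exact identity.

ASR itself makes one statistical assumption: that clean activity in every
principal direction has a stationary amplitude distribution whose location
and spread can be estimated from artifact-light stretches of the recording,
so that "larger than µ + k·σ" identifies artifact variance. The cut-off k
trades aggressiveness against signal preservation; k = 17 with the other
defaults below reproduces the reference configuration for this method.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `embed_dim` (M) | 90 | samples | rows of the Hankel matrix; 90 is the reference choice for 500 Hz. The helper `min_embedding_dimension(fs, fL) = ceil(fs/fL)` states the textbook lower bound for resolving a lowest frequency of interest; it is advisory — with fL = 0.5 Hz it would demand M ≥ 1000, far past the point where conditioning and runtime degrade, and in practice M = 90 cleans blink-band artifacts well. |
| `lag` | 1 | samples | delay between rows; reconstruction by anti-diagonal averaging requires 1 (larger lags are supported for embedding experiments only). |
| `cutoff_k` | 17 | — | multiplier in T_i = µ_i + k·σ_i; smaller removes more. |
| `calib_window` | 1.0 | s | non-overlapping windows for both the cleanliness screen and the threshold statistics. |
| `proc_window` | 0.5 | s | processing window length. |
| `z_low, z_high` | −3.5, 5.5 | z | strict bounds a window's every component must satisfy to count as clean calibration data. |
| `max_dims` | 2/3 | — | largest fraction of components removable in one window. |
| `band_lo, band_hi, notch_freq` | 0.5, 100, 50 | Hz | pre-processing chain (4th-order Butterworth band-pass, Q = 30 IIR notch, both forward–backward so the chain is zero-phase; no detrending). |

## Robust statistics in calibration

Two estimation choices matter and are deliberate:

- **Window screening uses robust z-scores** (median center, IQR-derived
  scale). With several comparable artifacts in one recording, a plain
  mean/std z-score saturates around z ≈ 3 — the outliers inflate the very
  yardstick they are measured with — and no window would ever be excluded.
- **Covariance, component space and thresholds are computed from the
  concatenated clean windows**, not from the raw recording. Otherwise the
  artifact direction itself becomes a principal axis with inflated variance
  statistics, raising the rejection bound exactly where the artifacts live.
  The per-component µ_i, σ_i are again robust (median, lower-quartile
  spread): any residual contamination — artifact tails straddling a window
  boundary can pass the z-test — sits in the upper tail of the window-RMS
  distribution and must not leak into the thresholds.

## Window handling

Processing windows overlap by 50% and are recombined with strictly positive
raised-cosine weights (normalized so that identity operators reproduce the
input exactly). Artifacts have no reason to align with a fixed window grid;
with disjoint windows an artifact straddling a boundary contributes only
half its variance to each side and can escape rejection, and the abrupt
operator change at a join leaves a discontinuity large enough for the blink
detector to count as an event. Plain non-overlapping concatenation remains
available (`blend_windows=False`). Within a window the rejection is
iterated (≤ 4 passes): the reconstructed window is re-scored against the
bounds, because a rank-3 artifact patch is not always fully captured by the
directions flagged in the first pass.

## Numerical choices

- Eigendecompositions use `eigh` (ascending order); eigenvector signs are
  fixed by making each column's largest-magnitude element positive. The
  reconstruction operator is mathematically invariant to these conventions
  (tested by randomizing signs).
- Only the top `max_dims` of a window's eigenvalue spectrum is removable,
  and never a direction carrying less than 1e-3 of the dominant calibration
  eigenvalue: an artifact *adds* variance, and removing a near-null
  direction makes the oblique reconstruction ill-posed.
- The truncated pseudoinverse uses a relative cutoff of 1e-6 — far below
  the smallest genuine singular value of `V_Tᵀ·M_C` (bounded by
  `sqrt(λmin/λmax)` of the calibration covariance) and far above the
  numerical residue of the zeroed rows, which the default machine-precision
  cutoff would otherwise invert into enormous amplification.
- Windows with nothing flagged short-circuit to the exact identity; with a
  very large k the whole pipeline is the identity to machine precision.
- A trailing partial window (non-blended mode) is cleaned with the last
  full window's operator so the output length always equals the input's.
- The PSD matrix square root clips eigenvalues in [−1e-10·λmax, 0] to zero
  and rejects materially indefinite or asymmetric input.

## The synthetic benchmark

`build_semisimulated` reproduces the standard semi-simulated protocol with
fully synthetic ingredients, so every test runs without any recorded data:

- **Clean EEG**: Gaussian noise spectrally shaped to a fixed per-band power
  budget for awake eyes-open prefrontal EEG — delta 0.23, theta 0.15,
  alpha 0.10 (half of it a 10 Hz sinusoidal rhythm), beta 0.41, gamma 0.11;
  flat density within each band, a 1%-amplitude broadband floor outside
  0.5–100 Hz standing in for measurement noise (it also keeps the embedded
  covariance full-rank), and the standard deviation normalized to exactly
  10 µV. Two distinct 10-s segments are replicated and concatenated into
  the 60-s ground truth.
- **Blinks**: a raised-cosine-squared deflection of ~0.3 s with a seeded
  ±10% rise/fall asymmetry inside a 2-s segment, peaking at 400 µV before
  mixing; ≥ 99% of its power lies below 20 Hz. Each template is zero-padded
  to 10 s at a position drawn uniformly from the central 70% of the segment
  — real blinks fall anywhere, and a fixed position would be artificially
  phase-locked to the cleaning windows.
- **Mixing**: per 10-s segment, z = s + α·m with α chosen so that
  SNR = 10·log10(RMS(s)/RMS(α·m)) equals a uniform draw from [−7, 2] dB
  (note the convention: 10·log of an *amplitude* ratio). The four
  (clean segment × blink template) pairings cycle in lexicographic order
  across the six segments, giving one blink per segment, six per minute.

What the generator does *not* emulate: non-stationary background (drowsiness,
movement), saccades and other ocular activity besides blinks, muscle and
cardiac artifacts, electrode pops, line noise, or the blink-rate and
blink-shape variability of real subjects. Passing the benchmark therefore
shows that the pipeline removes large low-frequency transients from a
stationary EEG-like background at controlled SNR — not that it handles every
real-world contamination.

## Known limitations

- Sensitivity at the top of the SNR range: a blink mixed at ≳ +1.5 dB has a
  peak of only ~60–80 µV over a 10 µV background, and its per-direction
  window variance can sit just below the k = 17 rejection bound even with
  ideal calibration. Across many generator seeds a small fraction of such
  weak blinks (roughly one seed in thirteen is affected) survives with a
  residual just above the detector threshold. This is the intrinsic
  discrimination limit of a variance test at k = 17, not an estimation
  failure.
- Offline batch operation: calibration uses the full recording; no
  streaming state update is provided.
- The delay-embedded covariance of band-limited signals is ill-conditioned
  by construction; very large embedding dimensions (toward `ceil(fs/fL)`
  with fL = 0.5 Hz) are not recommended.
- EDF export is 16-bit with 1-s records; signals are zero-padded to whole
  seconds and the sampling rate must be an integer.
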