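"""Artifact subspace reconstruction: calibration and sliding-window processing.

ASR is an adaptive spatial filter. Calibration learns, from the statistics of
the recording itself, how large each principal component of the data is
allowed to get; processing then eigendecomposes short windows, drops any
component whose window variance exceeds its learned bound, and reconstructs
the window from the surviving subspace.

Calibration (``asr_calibrate``):

1. score non-overlapping 1-s windows in the principal component space of the
   full recording: per-component window RMS, z-scored robustly (median
   center, interquartile scale) across windows; a window is clean iff every
   component's z-score lies strictly inside (z_low, z_high) = (−3.5, 5.5);
2. concatenate the clean windows — this is the calibration data;
3. covariance C of the calibration data; mixing matrix M_C = principal
   symmetric square root of C (M_C·M_Cᵀ = C); eigendecomposition of M_C →
   component directions V_C (ascending);
4. per-component RMS of the calibration data in 1-s windows → robust
   location µ_i and scale σ_i → rejection threshold T_i = µ_i + k·σ_i with
   cut-off parameter k (default 17; smaller k is more aggressive);
5. threshold matrix T = diag(T_i)·V_Cᵀ.

Processing (``asr_process``): each 0.5-s window is eigendecomposed
(V_T, D_T ascending); component j is flagged when its window variance
D_T[j] exceeds the squared projection of the threshold matrix onto that
eigenvector, Σ_m (T·V_T)²[m, j] — the amplitude thresholds T_i live on the
calibration axes, so they are rotated into the window's eigenbasis before
comparing with variances. Flagged directions are removed and the window is
rebuilt as

    X_clean = M_C · (V_Tᵀ·M_C)⁺_trunc · V_Tᵀ · X

where the truncated Moore–Penrose pseudoinverse zeroes the flagged rows;
with nothing flagged the operator is exactly the identity, and with
everything flagged it is zero. An artifact that straddles several principal
directions is not always caught in one pass, so the rejection is iterated:
the reconstructed window is re-scored against the bounds and further
directions are removed until the window satisfies every bound (at most a
few iterations in practice).

By default consecutive windows overlap by 50% and are recombined with a
raised-cosine (Hann) weighting. Artifacts have no reason to align with the
window grid; a non-overlapping segmentation halves the detectable variance
of anything that straddles a boundary and leaves small discontinuities at
the joins. Plain non-overlapping concatenation is available with
``blend_windows=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import (
    CalibrationError,
    DimensionError,
    InsufficientDataError,
    NumericDomainError,
)

__all__ = ["ASRParameters", "ASRState", "matrix_sqrt_psd", "asr_calibrate", "asr_process"]

#: Windows may only lose directions carrying at least this fraction of the
#: dominant calibration variance: near-null directions are never artifacts,
#: and removing one would make the oblique reconstruction ill-posed.
_REMOVABLE_VARIANCE_FLOOR = 1e-3

#: Relative pseudo-inverse cutoff: far below the smallest genuine singular
#: value of (V_Tᵀ·M_C) — bounded by sqrt(λmin/λmax) of the calibration
#: covariance — but far above the numerical residue of the zeroed rows.
_PINV_RCOND = 1e-6

_MAX_REJECT_ITERATIONS = 4


@dataclass(frozen=True)
class ASRParameters:
    """Tunable parameters of the ASR core.

    cutoff_k
        Multiplier of the clean-window RMS spread in the rejection threshold
        T_i = µ_i + k·σ_i. Smaller = more aggressive cleaning.
    calib_window
        Length (s) of the non-overlapping windows used both to score
        calibration-data cleanliness and to estimate threshold statistics.
    proc_window
        Length (s) of the processing windows.
    z_low, z_high
        Strict z-score bounds a window's every component must satisfy to
        count as clean calibration data.
    max_dims
        Largest fraction of components that may be removed in one window;
        only the top of the window's variance spectrum is removable.
    blend_windows
        Overlap processing windows by 50% and recombine with raised-cosine
        weights (default). False = non-overlapping concatenation.
    """

    cutoff_k: float = 17.0
    calib_window: float = 1.0
    proc_window: float = 0.5
    z_low: float = -3.5
    z_high: float = 5.5
    max_dims: float = 2 / 3
    blend_windows: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_k <= 0:
            raise NumericDomainError(f"cutoff_k must be > 0, got {self.cutoff_k}")
        if self.calib_window <= 0 or self.proc_window <= 0:
            raise NumericDomainError("window lengths must be positive")
        if self.z_low >= self.z_high:
            raise NumericDomainError(
                f"need z_low < z_high, got ({self.z_low}, {self.z_high})"
            )
        if not 0 < self.max_dims <= 1:
            raise NumericDomainError(f"max_dims must lie in (0, 1], got {self.max_dims}")


@dataclass
class ASRState:
    """Output of calibration: everything processing needs.

    Attributes
    ----------
    mixing
        M×M mixing matrix M_C (principal square root of the calibration
        covariance).
    eigvecs
        M×M matrix V_C whose columns are the calibration principal
        directions (ascending eigenvalue order).
    thresholds
        Per-component RMS-amplitude rejection thresholds T_i.
    threshold_matrix
        T = diag(T_i)·V_Cᵀ.
    n_calib_windows_used
        Number of windows that passed the z-score cleanliness test.
    """

    mixing: np.ndarray
    eigvecs: np.ndarray
    thresholds: np.ndarray
    threshold_matrix: np.ndarray
    n_calib_windows_used: int

    @property
    def n_channels(self) -> int:
        return int(self.mixing.shape[0])

    @property
    def max_calib_variance(self) -> float:
        """Largest eigenvalue of the calibration covariance M_C·M_Cᵀ."""
        return float(np.linalg.norm(self.mixing, 2) ** 2)

    def save(self, path: str | Path) -> Path:
        """Serialize the state to an .npz archive."""
        path = Path(path)
        np.savez(
            path,
            mixing=self.mixing,
            eigvecs=self.eigvecs,
            thresholds=self.thresholds,
            threshold_matrix=self.threshold_matrix,
            n_calib_windows_used=np.array([self.n_calib_windows_used]),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ASRState":
        with np.load(path) as archive:
            return cls(
                mixing=archive["mixing"],
                eigvecs=archive["eigvecs"],
                thresholds=archive["thresholds"],
                threshold_matrix=archive["threshold_matrix"],
                n_calib_windows_used=int(archive["n_calib_windows_used"][0]),
            )


def matrix_sqrt_psd(C: np.ndarray, sym_tol: float = 1e-8) -> np.ndarray:
    """Principal symmetric square root S of a PSD matrix, S·Sᵀ = C."""
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DimensionError(f"expected a square matrix, got shape {C.shape}")
    scale = max(np.abs(C).max(), 1.0)
    if np.abs(C - C.T).max() > sym_tol * scale:
        raise NumericDomainError("matrix is materially non-symmetric")
    eigvals, eigvecs = np.linalg.eigh((C + C.T) / 2.0)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
        raise NumericDomainError(
            f"matrix is indefinite (min eigenvalue {eigvals.min():.3e})"
        )
    eigvals = np.clip(eigvals, 0.0, None)
    return (eigvecs * np.sqrt(eigvals)) @ eigvecs.T


def _fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    # deterministic sign convention: largest-|.| element of each column positive
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _window_rms(Y: np.ndarray, win: int) -> np.ndarray:
    """Per-component RMS over non-overlapping windows: (components, windows)."""
    n_comp, n_samp = Y.shape
    n_win = n_samp // win
    trimmed = Y[:, : n_win * win].reshape(n_comp, n_win, win)
    return np.sqrt(np.mean(trimmed**2, axis=2))


def asr_calibrate(
    X: np.ndarray, fs: float, params: ASRParameters | None = None
) -> ASRState:
    """Learn per-component rejection thresholds from a channels × samples matrix.

    Raises
    ------
    InsufficientDataError
        If the data hold fewer than two calibration windows.
    CalibrationError
        If no window passes the z-score cleanliness test.
    """
    params = params or ASRParameters()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DimensionError(f"need a 2-D matrix with >= 2 rows, got shape {X.shape}")
    win = int(round(fs * params.calib_window))
    n_windows = X.shape[1] // win
    if n_windows < 2:
        raise InsufficientDataError(
            f"calibration needs >= 2 windows of {win} samples; got {X.shape[1]} samples"
        )

    # Pass 1 — score windows in the component space of the full recording.
    # Robust z-scores: artifact windows must not inflate the location/scale
    # they are judged against (with several comparable artifacts a plain std
    # saturates every z-score below any usable bound), so the center is the
    # median and the scale comes from the interquartile range.
    Xc = X - X.mean(axis=1, keepdims=True)
    C0 = (Xc @ Xc.T) / Xc.shape[1]
    _, V0 = np.linalg.eigh(matrix_sqrt_psd(C0))
    rms0 = _window_rms(V0.T @ X, win)  # (components, windows)
    center = np.median(rms0, axis=1, keepdims=True)
    q75, q25 = np.percentile(rms0, [75, 25], axis=1)
    scale = ((q75 - q25) / 1.349)[:, None]
    fallback = rms0.std(axis=1, keepdims=True)
    scale = np.where(scale > 0, scale, fallback)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(scale > 0, (rms0 - center) / scale, 0.0)
    clean = np.all((z > params.z_low) & (z < params.z_high), axis=0)
    n_clean = int(clean.sum())
    if n_clean == 0:
        raise CalibrationError(
            f"no clean calibration windows: all {n_windows} windows have a "
            f"component z-score outside ({params.z_low}, {params.z_high})"
        )

    # Pass 2 — the clean windows, concatenated, are the calibration data;
    # mixing matrix, component space and thresholds all describe *clean*
    # signal geometry. (Computing them on the raw recording instead would
    # make the artifact direction itself a principal axis with inflated
    # variance statistics, raising the rejection bounds exactly where the
    # artifacts live.)
    windows = X[:, : n_windows * win].T.reshape(n_windows, win, X.shape[0])
    calib = windows[clean].reshape(n_clean * win, X.shape[0]).T
    calib_c = calib - calib.mean(axis=1, keepdims=True)
    C = (calib_c @ calib_c.T) / calib_c.shape[1]
    M_C = matrix_sqrt_psd(C)
    _, V_C = np.linalg.eigh(M_C)
    V_C = _fix_eigvec_signs(V_C)

    # Per-component location/scale of the clean-window RMS values, again
    # robust: residual contamination (artifact tails straddling a window
    # boundary can pass the z-test) lives in the upper tail, so sigma comes
    # from the lower quartile spread (Gaussian: q50 − q25 = 0.6745·σ).
    rms_c = _window_rms(V_C.T @ calib, win)
    mu = np.median(rms_c, axis=1)
    q25c = np.percentile(rms_c, 25, axis=1)
    sigma = (mu - q25c) / 0.6745
    sigma = np.where(sigma > 0, sigma, rms_c.std(axis=1))
    thresholds = mu + params.cutoff_k * sigma
    threshold_matrix = np.diag(thresholds) @ V_C.T
    return ASRState(
        mixing=M_C,
        eigvecs=V_C,
        thresholds=thresholds,
        threshold_matrix=threshold_matrix,
        n_calib_windows_used=n_clean,
    )


def _window_operator(
    W: np.ndarray, state: ASRState, max_dims: float, var_floor: float
) -> np.ndarray | None:
    """Reconstruction operator R for one processing window (X_clean = R·X).

    Returns None when nothing is flagged (the identity). The rejection is
    iterated: directions are removed until the reconstructed window
    satisfies every bound.
    """
    m = W.shape[0]
    n_removable = int(np.floor(max_dims * m))
    R_total: np.ndarray | None = None
    W_cur = W
    for _ in range(_MAX_REJECT_ITERATIONS):
        C_T = (W_cur @ W_cur.T) / W_cur.shape[1]
        D_T, V_T = np.linalg.eigh((C_T + C_T.T) / 2.0)
        V_T = _fix_eigvec_signs(V_T)
        bounds = np.sum((state.threshold_matrix @ V_T) ** 2, axis=0)
        # An artifact adds variance: only the top max_dims fraction of the
        # window spectrum is removable, and never a direction carrying less
        # variance than the removable floor.
        keep = (
            (D_T <= bounds)
            | (np.arange(m) < m - n_removable)
            | (D_T <= var_floor)
        )
        if keep.all():
            break
        if not keep.any():
            return np.zeros((m, m))
        S = V_T.T @ state.mixing
        S = S * keep[:, None]         # zero the flagged component rows
        R = state.mixing @ np.linalg.pinv(S, rcond=_PINV_RCOND) @ V_T.T
        R_total = R if R_total is None else R @ R_total
        W_cur = R @ W_cur
    return R_total


def asr_process(
    X: np.ndarray,
    state: ASRState,
    params: ASRParameters | None = None,
    fs: float | None = None,
) -> np.ndarray:
    """Clean a channels × samples matrix with a calibrated state.

    The output has exactly the input shape. With ``blend_windows`` (default)
    50%-overlapping windows are recombined with raised-cosine weights;
    otherwise windows are non-overlapping and concatenated, and a trailing
    partial window is cleaned with the last full window's operator.
    """
    params = params or ASRParameters()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != state.n_channels:
        raise DimensionError(
            f"data shape {X.shape} does not match calibration ({state.n_channels} channels)"
        )
    if fs is None:
        raise DimensionError("fs must be provided to size the processing windows")
    win = int(round(fs * params.proc_window))
    n = X.shape[1]
    if n < win:
        raise InsufficientDataError(
            f"need at least one full {win}-sample processing window, got {n}"
        )
    var_floor = _REMOVABLE_VARIANCE_FLOOR * state.max_calib_variance

    if not params.blend_windows:
        out = np.empty_like(X)
        n_full = n // win
        operator: np.ndarray | None = None
        for w in range(n_full):
            sl = slice(w * win, (w + 1) * win)
            operator = _window_operator(X[:, sl], state, params.max_dims, var_floor)
            out[:, sl] = X[:, sl] if operator is None else operator @ X[:, sl]
        rest = slice(n_full * win, n)
        if n > n_full * win:
            out[:, rest] = X[:, rest] if operator is None else operator @ X[:, rest]
        return out

    hop = max(1, win // 2)
    starts = list(range(0, n - win + 1, hop))
    if starts[-1] != n - win:
        starts.append(n - win)
    taper = np.hanning(win + 2)[1:-1]   # strictly positive so edges stay covered
    out = np.zeros_like(X)
    weight = np.zeros(n)
    for s in starts:
        sl = slice(s, s + win)
        operator = _window_operator(X[:, sl], state, params.max_dims, var_floor)
        segment = X[:, sl] if operator is None else operator @ X[:, sl]
        out[:, sl] += segment * taper
        weight[sl] += taper
    weight[weight == 0] = 1.0
    return out / weight
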