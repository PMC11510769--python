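"""Delay embedding of a single channel and its inverse.

A 1-D signal x(1..N) is turned into the M×K Hankel matrix

    X = [ x(1) x(2) ... x(K)   ]
        [ x(2) x(3) ... x(K+1) ]
        [  :                :  ]
        [ x(M) ...      x(N)   ]

with K = N − M + 1 (unit lag): each row is a lagged copy of the signal, so the
matrix acts as a pseudo-multichannel recording that a spatial filter such as
ASR can operate on. The inverse map is anti-diagonal averaging (the SSA
"Hankelization" step): sample t of the reconstructed signal is the mean of all
matrix entries on the anti-diagonal i + j = t (0-based), which is the
least-squares-closest signal to an arbitrary (no longer Hankel) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DimensionError
from .timeseries import TimeSeries

__all__ = ["EmbeddedMatrix", "embed", "hankelize", "min_embedding_dimension"]


@dataclass(frozen=True)
class EmbeddedMatrix:
    """M×K delay matrix of a 1-D signal (rows = lagged copies = pseudo-channels)."""

    values: np.ndarray
    lag: int
    fs: float
    label: str = "EEG"

    @property
    def M(self) -> int:
        """Embedding dimension (number of rows)."""
        return int(self.values.shape[0])

    @property
    def K(self) -> int:
        """Number of delay vectors (columns)."""
        return int(self.values.shape[1])

    @property
    def source_length(self) -> int:
        """Length N of the signal the matrix was built from."""
        return self.K + (self.M - 1) * self.lag


def embed(ts: TimeSeries | np.ndarray, M: int, lag: int = 1, fs: float | None = None) -> EmbeddedMatrix:
    """Delay-embed a signal into an M-row Hankel matrix.

    Row i (0-based) is ``x[i*lag : i*lag + K]`` with ``K = N − (M−1)·lag``;
    for the default unit lag this is the classic Hankel layout with
    ``K = N − M + 1``.
    """
    if isinstance(ts, TimeSeries):
        x, fs, label = ts.samples, ts.fs, ts.label
    else:
        x = np.asarray(ts, dtype=np.float64)
        fs = 1.0 if fs is None else fs
        label = "EEG"
    n = x.size
    if lag < 1:
        raise DimensionError(f"lag must be >= 1, got {lag}")
    if not 1 <= M <= n:
        raise DimensionError(f"embedding dimension M={M} must lie in [1, N={n}]")
    if (M - 1) * lag >= n:
        raise DimensionError(f"(M-1)*lag = {(M - 1) * lag} must be < N = {n}")
    K = n - (M - 1) * lag
    stride = x.strides[0]
    values = np.lib.stride_tricks.as_strided(
        x, shape=(M, K), strides=(lag * stride, stride)
    ).copy()
    return EmbeddedMatrix(values=values, lag=lag, fs=float(fs), label=label)


def hankelize(em: EmbeddedMatrix | np.ndarray, fs: float | None = None, label: str | None = None) -> TimeSeries:
    """Invert a (possibly perturbed) unit-lag embedding by anti-diagonal averaging.

    Sample t of the output is the mean of all entries (i, j) with i + j = t;
    for an exactly Hankel matrix this recovers the original signal exactly.
    Only defined for lag 1.
    """
    if isinstance(em, EmbeddedMatrix):
        if em.lag != 1:
            raise DimensionError("anti-diagonal averaging requires lag = 1")
        values = em.values
        fs = em.fs if fs is None else fs
        label = em.label if label is None else label
    else:
        values = np.asarray(em, dtype=np.float64)
        fs = 1.0 if fs is None else fs
        label = "EEG" if label is None else label
    if values.ndim != 2:
        raise DimensionError("expected a 2-D matrix")
    m, k = values.shape
    n = m + k - 1
    idx = (np.arange(m)[:, None] + np.arange(k)[None, :]).ravel()
    sums = np.bincount(idx, weights=values.ravel(), minlength=n)
    counts = np.bincount(idx, minlength=n)
    return TimeSeries(samples=sums / counts, fs=float(fs), label=label)


def min_embedding_dimension(fs: float, fL: float) -> int:
    """Smallest embedding dimension resolving the lowest frequency of interest.

    Returns ``ceil(fs / fL)``, the smallest integer M with M ≥ fs/fL. This is
    an advisory rule of thumb — the pipeline's default M = 90 at fs = 500 Hz
    is an empirical choice that trades depth for conditioning and speed.
    """
    if fL <= 0:
        raise ConfigurationError(f"lowest frequency of interest must be > 0, got {fL}")
    if fs <= 0:
        raise ConfigurationError(f"sampling rate must be > 0, got {fs}")
    if fL >= fs / 2:
        raise ConfigurationError(f"fL={fL} must be below Nyquist ({fs / 2})")
    return int(np.ceil(fs / fL))
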