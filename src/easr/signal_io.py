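"""Reading and writing single-channel EEG signals.

Supported on the way in: EDF/EDF+ and BDF (24-bit BioSemi) via MNE, and plain
CSV (a single numeric column, optional one-line header; the sampling rate must
be supplied since CSV has no header metadata). On the way out: CSV and EDF.

The EDF writer is a minimal, self-contained implementation of the 16-bit EDF
record format for one channel: 1-second data records, a symmetric physical
range spanning the signal, and zero-padding of the last partial record. It is
round-trip checked against MNE's independent EDF reader in the test suite.
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ChannelNotFoundError, ConfigurationError, FormatError
from .timeseries import TimeSeries

__all__ = ["read_signal", "write_signal"]

_EDF_DIG_MAX = 32767


def _infer_format(path: os.PathLike | str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"edf", "bdf", "csv"}:
        return suffix
    raise FormatError(f"cannot infer signal format from {path!r}; pass format=")


def read_signal(
    path: os.PathLike | str,
    channel: str | None = None,
    fs: float | None = None,
    format: str | None = None,
) -> TimeSeries:
    """Read one channel from an EDF/BDF/CSV file as a :class:`TimeSeries` in µV.

    Parameters
    ----------
    path
        Input file. Format is inferred from the extension unless ``format``
        is given.
    channel
        Channel label to extract (EDF/BDF). May be omitted for single-channel
        files and is ignored for CSV.
    fs
        Sampling rate in Hz — required for CSV, ignored for EDF/BDF (taken
        from the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path, fs)
    if fmt in {"edf", "bdf"}:
        return _read_biosignal(path, channel, fmt)
    raise FormatError(f"unsupported format {fmt!r}")


def _read_csv(path: Path, fs: float | None) -> TimeSeries:
    if fs is None:
        raise ConfigurationError("CSV carries no sampling rate; fs must be supplied")
    try:
        raw = pd.read_csv(path, sep=r"[,;\t]", engine="python", header=None)
    except Exception as exc:  # pragma: no cover - pandas raises many subclasses
        raise FormatError(f"could not parse {path} as CSV: {exc}") from exc
    if raw.shape[1] != 1:
        raise FormatError(
            f"{path} has {raw.shape[1]} columns; expected a single numeric column"
        )
    col = raw.iloc[:, 0]
    label = "EEG"
    try:
        float(col.iloc[0])
    except (TypeError, ValueError):
        label = str(col.iloc[0]).strip()
        col = col.iloc[1:]
    try:
        samples = col.astype(np.float64).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric values in {path}") from exc
    return TimeSeries(samples=samples, fs=float(fs), label=label)


def _read_biosignal(path: Path, channel: str | None, fmt: str) -> TimeSeries:
    import mne

    reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as {fmt.upper()}: {exc}") from exc
    if channel is None:
        if len(raw.ch_names) != 1:
            raise ConfigurationError(
                f"{path} holds channels {raw.ch_names}; specify one"
            )
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path} (available: {raw.ch_names})"
        )
    data = raw.get_data(picks=[channel])[0] * 1e6  # MNE returns volts
    return TimeSeries(samples=data, fs=float(raw.info["sfreq"]), label=channel)


def write_signal(ts: TimeSeries, path: os.PathLike | str, format: str | None = None) -> Path:
    """Write a :class:`TimeSeries` to CSV or EDF (16-bit).

    CSV output is one header line (the channel label) followed by one sample
    per row. EDF output quantizes to 16 bits over a symmetric physical range
    covering the signal and pads the final partial second with zeros.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"{ts.label}\n")
            np.savetxt(fh, ts.samples, fmt="%.10g")
        return path
    if fmt == "edf":
        _write_edf(ts, path)
        return path
    raise FormatError(f"cannot write format {fmt!r} (supported: csv, edf)")


def _ascii_field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} chars")
    return text.ljust(width).encode("ascii")


def _write_edf(ts: TimeSeries, path: Path) -> None:
    fs = ts.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError(
            f"EDF export uses 1-s records; sampling rate must be an integer, got {fs}"
        )
    fs = int(round(fs))
    n_records = int(np.ceil(ts.n_samples / fs))
    padded = np.zeros(n_records * fs)
    padded[: ts.n_samples] = ts.samples

    # Symmetric physical range; re-parse the printed value so the scale the
    # reader reconstructs is exactly the one used for quantization.
    phys_max = float(f"{max(np.abs(padded).max(), 1e-6) * 1.0001:.6g}")
    digital = np.clip(
        np.round(padded / phys_max * _EDF_DIG_MAX), -_EDF_DIG_MAX, _EDF_DIG_MAX
    ).astype("<i2")

    header = io.BytesIO()
    header.write(_ascii_field("0", 8))                    # version
    header.write(_ascii_field("X X X X", 80))             # patient id
    header.write(_ascii_field("Startdate X X X X", 80))   # recording id
    header.write(_ascii_field("01.01.00", 8))             # start date
    header.write(_ascii_field("00.00.00", 8))             # start time
    header.write(_ascii_field(256 * 2, 8))                # header bytes
    header.write(_ascii_field("", 44))                    # reserved
    header.write(_ascii_field(n_records, 8))
    header.write(_ascii_field(1, 8))                      # record duration (s)
    header.write(_ascii_field(1, 4))                      # number of signals
    header.write(_ascii_field(ts.label[:16], 16))
    header.write(_ascii_field("", 80))                    # transducer
    header.write(_ascii_field("uV", 8))
    header.write(_ascii_field(f"{-phys_max:.6g}", 8))
    header.write(_ascii_field(f"{phys_max:.6g}", 8))
    header.write(_ascii_field(-_EDF_DIG_MAX, 8))
    header.write(_ascii_field(_EDF_DIG_MAX, 8))
    header.write(_ascii_field("", 80))                    # prefiltering
    header.write(_ascii_field(fs, 8))                     # samples per record
    header.write(_ascii_field("", 32))                    # reserved

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        fh.write(digital.tobytes())
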