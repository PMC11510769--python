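"""Exception hierarchy for the easr package.

All package errors derive from :class:`EASRError` so callers (and the CLI)
can catch domain failures in one place without swallowing programming errors.
"""


class EASRError(Exception):
    """Base class for all easr domain errors."""


class ConfigurationError(EASRError, ValueError):
    """A parameter value is invalid (bad frequency, missing sampling rate, ...)."""


class FormatError(EASRError, ValueError):
    """A file could not be parsed in the requested format."""


class ChannelNotFoundError(EASRError, KeyError):
    """The requested channel label is not present in the file."""


class DimensionError(EASRError, ValueError):
    """Array shapes or embedding dimensions are inconsistent."""


class InsufficientDataError(EASRError, ValueError):
    """The signal is too short for the requested operation."""


class CalibrationError(EASRError, RuntimeError):
    """ASR calibration could not find any clean windows."""


class NumericDomainError(EASRError, ValueError):
    """A numeric precondition is violated (non-PSD matrix, zero RMS, ...)."""
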