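"""Exception hierarchy for eegpathlab.

All package errors derive from :class:`EEGPathLabError` so callers (and the
CLI) can distinguish validation problems (exit code 2) from data problems
(exit code 3).
"""


class EEGPathLabError(Exception):
    """Base class for all package errors."""


class ValidationError(EEGPathLabError, ValueError):
    """A spec/config/argument failed validation; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataError(EEGPathLabError):
    """Base class for problems with input data rather than configuration."""


class EDFParseError(DataError):
    """The file is not readable as EDF."""


class UnsupportedInputError(DataError):
    """Structurally valid input the pipeline does not support."""


class MissingChannelError(DataError):
    """A montage channel is absent from the recording."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"montage channel {label!r} not present in recording")


class UpsamplingRefusedError(DataError):
    """Recording sampling rate is below the requested target rate."""


class InsufficientDurationError(DataError):
    """Recording too short to yield the requested number of segments."""


class DecompositionError(DataError):
    """Input too short for the requested wavelet decomposition depth."""


class LeakageError(EEGPathLabError):
    """Train and test splits share recording identifiers."""
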