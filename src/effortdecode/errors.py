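"""Exception hierarchy for the decoding pipeline."""


class EffortDecodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EffortDecodeError, ValueError):
    """A session or run configuration field is invalid."""


class FormatError(EffortDecodeError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ScheduleError(EffortDecodeError, ValueError):
    """An event schedule is malformed (overlaps, inverted segments...)."""


class PreprocessingError(EffortDecodeError, ValueError):
    """A preprocessing step received data it cannot handle."""


class FitError(EffortDecodeError, ValueError):
    """Model fitting preconditions are violated."""


class NumericError(EffortDecodeError, ArithmeticError):
    """A numerical routine degenerated (singular covariance, NaN...)."""


class UsageError(EffortDecodeError, ValueError):
    """An operation was called with inconsistent arguments."""
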