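"""Exception hierarchy for the trait-network pipeline.

Every anticipated failure mode raises a subclass of :class:`PTNError`
so callers can distinguish bad configuration from bad data.
"""


class PTNError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PTNError):
    """A configuration value is missing, malformed, or out of range."""


class FormatError(PTNError):
    """An input file does not have the expected shape or columns."""


class DomainError(PTNError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InsufficientDataError(PTNError):
    """Too few observations to compute the requested statistic."""


class UndefinedCVError(PTNError):
    """Coefficient of variation is undefined (zero mean)."""


class DegenerateNetworkError(PTNError):
    """The network is too small for the requested metric."""


class CollinearityError(PTNError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class JoinError(PTNError):
    """Keys fail to match when merging tables."""

    def __init__(self, message: str, unmatched: list | None = None):
        super().__init__(message)
        self.unmatched = unmatched or []
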