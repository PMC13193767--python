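"""Exception hierarchy shared across the package."""


class SeedAssayError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SeedAssayError, ValueError):
    """A scalar argument violates its precondition (sign, range, count)."""


class InputFormatError(SeedAssayError, ValueError):
    """A file or string could not be parsed in the expected format."""


class InsufficientDataError(SeedAssayError, ValueError):
    """Too few (distinct) data points for the requested fit."""


class ConfigurationError(SeedAssayError, ValueError):
    """A simulation or audit configuration is inconsistent or incomplete."""
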