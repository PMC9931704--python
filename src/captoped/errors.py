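"""Exception hierarchy.

Every error raised by this package derives from :class:`CaptopedError`, so
callers (and the CLI, which maps branches to exit codes) can distinguish bad
parameter values, bad configuration, bad data and numerical failures.
"""


class CaptopedError(Exception):
    """Base class for all package errors."""


class DomainError(CaptopedError, ValueError):
    """A scalar argument is outside its physical/mathematical domain."""


class ConfigError(CaptopedError):
    """Invalid or unsatisfiable configuration (CLI exit code 2)."""


class UnsupportedStageError(ConfigError):
    """A CKD stage with no disease parameterization was requested."""


class DataError(CaptopedError):
    """Malformed or missing input data (CLI exit code 3)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested computation."""


class AlignmentError(DataError):
    """Profiles/summaries do not share a common time grid."""


class NumericalError(CaptopedError):
    """ODE solver failure or non-finite state (CLI exit code 4)."""
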