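"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: configuration errors -> 2, data errors -> 3,
numerical failures -> 4.
"""


class PresymptoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PresymptoError):
    """An invalid configuration value; the message names the violated invariant."""


class DataError(PresymptoError):
    """Malformed or inconsistent input data."""


class NumericalError(PresymptoError):
    """A numerical failure (divergence, singular system, failed residual check)."""
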