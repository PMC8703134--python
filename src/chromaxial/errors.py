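"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 1, :class:`DataError` -> 2,
:class:`ModelInsufficientError` -> 3.
"""


class ChromaxialError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class DataError(ChromaxialError):
    """Malformed, inconsistent or degenerate input data."""

    exit_code = 2


class ModelInsufficientError(ChromaxialError):
    """A calibration model failed the statistical power gate."""

    exit_code = 3
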