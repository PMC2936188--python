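"""Exception hierarchy.

Exit-code mapping used by the CLI: validation problems exit 2, file-format
problems exit 3, anything else 1.
"""


class VolprecError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class ValidationError(VolprecError):
    """A domain object violates an invariant (bad contour, bad series, ...)."""

    exit_code = 2


class InsufficientDataError(ValidationError):
    """Too few measurements for the requested statistic."""


class FormatError(VolprecError):
    """An on-disk file does not match the expected CSV schema."""

    exit_code = 3
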