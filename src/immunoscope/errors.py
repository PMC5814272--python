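"""Exception hierarchy.

``DataError`` subclasses map to CLI exit status 2; ``ConfigError`` and
plain usage problems map to exit status 1.
"""


class ImmunoscopeError(Exception):
    """Base class for all package errors."""


class ConfigError(ImmunoscopeError):
    """Invalid configuration value or combination."""


class DataError(ImmunoscopeError):
    """Problem with input data content."""


class FormatError(DataError):
    """Structural problem with an input file (missing column, bad header...)."""


class RecordError(DataError):
    """A single record violates an invariant; carries the row number when known."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


class UndefinedScoreError(DataError):
    """An enrichment score is undefined (gene set disjoint from ranked list)."""


class VariantRejectedError(DataError):
    """A protein variant is inconsistent with its reference sequence."""
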