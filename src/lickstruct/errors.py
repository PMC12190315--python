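"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`LickstructError` so callers
(including the CLI) can map them onto exit codes without matching on
library-internal exception types.
"""


class LickstructError(Exception):
    """Base class for all package errors."""


class ValidationError(LickstructError, ValueError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A delimited file is missing required columns or has a bad header."""


class ParseError(ValidationError):
    """A row of an on-disk artifact could not be parsed.

    Carries the 1-based file line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InternalConsistencyError(LickstructError):
    """Cross-referenced in-memory structures disagree (a bug, not bad input)."""


class ConvergenceError(LickstructError):
    """An iterative fit failed to converge; message includes the trace."""
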