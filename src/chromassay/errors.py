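"""Exception hierarchy for chromassay.

Every error raised by the package derives from :class:`ChromassayError`
so CLI entry points can catch one type and exit nonzero with a
one-line reason.
"""


class ChromassayError(Exception):
    """Base class for all chromassay errors."""


class ParameterError(ChromassayError, ValueError):
    """An argument is outside its documented domain."""


class PackingError(ChromassayError):
    """A nucleosome array cannot be placed at the requested density."""


class RangeError(ChromassayError, ValueError):
    """A fragment length falls outside the calibrated range of a gel model."""


class BandNotFoundError(ChromassayError):
    """A requested band window contains no profile support.

    Distinct from a band of zero height, which is a valid measurement.
    """


class DegenerateProfileError(ChromassayError):
    """Peaks coincide or leave no strictly-interior valley region."""


class FitFailureError(ChromassayError):
    """Nonlinear fit failed to converge after multi-start; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedResultError(ChromassayError):
    """A quantity is mathematically undefined for the given input (e.g. 0/0)."""


class ComparabilityError(ChromassayError):
    """Two results were quantified under incompatible settings."""


class ParseError(ChromassayError):
    """A file does not conform to the declared schema."""

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        detail = message
        if column is not None:
            detail += f" (column: {column})"
        if line is not None:
            detail += f" (line: {line})"
        super().__init__(detail)
        self.line = line
        self.column = column
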