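"""Exception hierarchy for craniomat.

All errors raised by the library derive from :class:`CraniomatError` so that
callers (and the CLI) can distinguish validation failures from programming
errors.  Most subclasses also inherit from ``ValueError`` because they signal
invalid numerical input.
"""


class CraniomatError(Exception):
    """Base class for all craniomat errors."""


class DomainError(CraniomatError, ValueError):
    """An argument lies outside the physical domain of an operation
    (e.g. a non-positive stretch ratio or a non-positive head mass)."""


class AgeRangeError(DomainError):
    """An age falls outside the validity range of an age-dependent model."""


class DegenerateFitError(CraniomatError, ValueError):
    """The data cannot constrain a fit (e.g. an all-zero stress curve)."""


class InsufficientDataError(CraniomatError, ValueError):
    """Too few samples, or samples without enough spread, for a fit."""


class StabilityError(CraniomatError, ValueError):
    """An assembled elastic-constant set violates material stability
    (compliance matrix not symmetric positive definite)."""


class UndefinedScoreError(CraniomatError, ValueError):
    """A correlation score is undefined (identically-zero reference)."""


class ParseError(CraniomatError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
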