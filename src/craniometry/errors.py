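"""Exception types shared across the package."""


class CraniometryError(Exception):
    """Base class for all package errors."""


class ParseError(CraniometryError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(CraniometryError):
    """Input data violates the landmark schema or a container invariant."""


class InsufficientLandmarksError(CraniometryError):
    """Too few landmarks are present to perform a geometric fit."""


class DegenerateGeometryError(CraniometryError):
    """Landmark configuration is degenerate (collinear/coincident points)."""
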