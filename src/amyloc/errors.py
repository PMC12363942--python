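"""Exception hierarchy shared across the package."""


class AmylocError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AmylocError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(AmylocError, RuntimeError):
    """An operation was invoked on an object in the wrong state."""


class UndefinedValueError(AmylocError, ValueError):
    """The requested quantity is mathematically undefined for this input."""


class ParseError(AmylocError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
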