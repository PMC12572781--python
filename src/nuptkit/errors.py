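"""Exception hierarchy shared across the package."""


class NuptkitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NuptkitError):
    """Invalid simulation or run configuration."""


class InputError(NuptkitError):
    """Invalid data handed to an operation (coordinates, ranges, values)."""


class ParseError(NuptkitError):
    """Malformed input file; carries the offending row/line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StatisticsError(NuptkitError):
    """A statistic is undefined or a sample is too small to fit."""


class GenerationError(NuptkitError):
    """The simulator could not satisfy the requested configuration."""
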