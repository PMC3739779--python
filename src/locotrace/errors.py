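"""Exception types shared across the package."""


class LocotraceError(Exception):
    """Base class for package errors."""


class ConfigurationError(LocotraceError):
    """Inconsistent configuration, e.g. profile and session stage disagree."""


class ValidationError(LocotraceError, ValueError):
    """Invalid domain values (negative durations, out-of-range thresholds...)."""


class ParseError(LocotraceError, ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
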