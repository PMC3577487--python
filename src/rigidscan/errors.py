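"""Exception types shared across the package."""


class RigidScanError(Exception):
    """Base class for all rigidscan errors."""


class ParseError(RigidScanError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(RigidScanError):
    """An input violated a documented precondition."""
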