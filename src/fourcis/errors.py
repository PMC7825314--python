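"""Exception hierarchy shared across the package."""


class FourCisError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FourCisError, ValueError):
    """Invalid input data or parameters."""


class ParseError(FourCisError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class FitError(FourCisError, RuntimeError):
    """A model fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
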