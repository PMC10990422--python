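"""Exception types shared across the package."""


class StrDenovoError(Exception):
    """Base class for package errors."""


class ConfigurationError(StrDenovoError):
    """Invalid simulation or analysis configuration."""


class FitError(StrDenovoError):
    """A model fit failed or produced invalid fitted values."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedRateError(StrDenovoError):
    """A rate or metric is undefined for the given input (distinct from zero)."""
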