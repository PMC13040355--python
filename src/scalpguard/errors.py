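"""Exception types shared across the package."""


class ScalpGuardError(Exception):
    """Base class for package errors."""


class ConfigurationError(ScalpGuardError):
    """A configuration field is missing, malformed, or inconsistent."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SchemaError(ScalpGuardError):
    """An event log or table violates the documented schema."""


class FittingError(ScalpGuardError):
    """Model estimation cannot proceed (missing class, singular covariance...)."""
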