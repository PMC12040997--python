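"""Exception hierarchy shared across the package."""


class MKLabourError(Exception):
    """Base class for package errors."""


class ConfigurationError(MKLabourError):
    """An invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ValidationError(MKLabourError):
    """Input data failed schema or structural validation."""


class NumericalError(MKLabourError):
    """A numerical invariant (e.g., kernel positive semidefiniteness) failed."""
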