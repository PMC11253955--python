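"""Exception types shared across the pipeline."""


class SSBTaxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SSBTaxError):
    """A configuration value is invalid; the message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ValidationError(SSBTaxError):
    """An input record is outside the accepted domain."""


class EstimationError(SSBTaxError):
    """A regression could not be estimated (singularity, too few rows, ...)."""
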