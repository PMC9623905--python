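"""Exception hierarchy for configuration and model errors."""


class CKDCEAError(Exception):
    """Base class for all package errors."""


class ConfigError(CKDCEAError):
    """A configuration file could not be loaded or validated."""


class MissingParameterError(ConfigError):
    """A required parameter is absent; the message names the field."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing required parameter: {field!r}")


class RangeError(ConfigError):
    """A parameter value lies outside its admissible range."""

    def __init__(self, field: str, value, detail: str):
        self.field = field
        self.value = value
        super().__init__(f"value {value!r} for {field!r} out of range: {detail}")


class UnknownReferenceError(ConfigError):
    """A state, curve, or parameter id that does not exist was referenced."""

    def __init__(self, ref: str):
        self.ref = ref
        super().__init__(f"unknown reference: {ref!r}")


class DomainError(CKDCEAError, ValueError):
    """A runtime argument (age, probability, rate, ...) is outside its domain."""


class ModelConstructionError(CKDCEAError):
    """A transition matrix could not be built from internally inconsistent inputs."""
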