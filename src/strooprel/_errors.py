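"""Exception hierarchy shared across the package."""


class StroopRelError(Exception):
    """Base class for all package errors."""


class SchemaError(StroopRelError):
    """A table is structurally invalid (missing column, inconsistent arm...)."""


class RowError(StroopRelError):
    """A single row violates an invariant under strict parsing."""


class ParameterError(StroopRelError, ValueError):
    """A parameter value is outside its admissible range."""


class ConfigError(StroopRelError):
    """A run configuration failed validation."""

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
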