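"""Exception types shared across the package."""


class VinefluxError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VinefluxError, ValueError):
    """A physically or numerically invalid input value."""


class ConfigurationError(VinefluxError, ValueError):
    """An inconsistent or incomplete run configuration."""


class SchemaError(VinefluxError, ValueError):
    """An input table does not conform to the expected column schema."""


class DegenerateFitError(VinefluxError, RuntimeError):
    """A model fit that cannot be carried out (e.g. constant response)."""
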