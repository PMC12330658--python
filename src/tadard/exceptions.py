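"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid simulation or analysis configuration."""


class SchemaError(ValueError):
    """An input table is missing required columns or contains bad values."""
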