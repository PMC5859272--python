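"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model parameter violates its documented bound."""


class ConfigError(ValueError):
    """A configuration file is malformed or contains unknown/invalid keys."""


class SchemaError(ValueError):
    """A tabular input does not match the expected clonal-dataset schema."""
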