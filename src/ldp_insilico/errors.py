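"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A distribution spec, policy, or constants block is invalid."""


class ValidationError(ValueError):
    """An input value violates a physical or contract bound."""
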