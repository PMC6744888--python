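"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration object violates one of its invariants."""


class InputError(ValueError):
    """Input data violate a precondition of an operation."""


class FittingError(RuntimeError):
    """Model fitting failed to produce any usable solution."""
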