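"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A simulation or run configuration violates its invariants."""


class InputError(ValueError):
    """An input table violates a precondition (mismatched keys, bad range)."""
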