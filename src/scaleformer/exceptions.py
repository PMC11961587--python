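"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A model/block configuration is internally inconsistent."""


class ShapeError(ValueError):
    """An input array has an incompatible shape."""
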