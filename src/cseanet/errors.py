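"""Package exception types."""


class ConfigurationError(ValueError):
    """A model/pipeline hyperparameter violates a structural constraint."""


class ShapeError(ValueError):
    """Arrays passed to an operation have incompatible shapes."""
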