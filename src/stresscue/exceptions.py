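"""Exception types raised by the package."""


class SchemaError(ValueError):
    """A table or file does not follow the expected schema."""


class IncompleteDataError(ValueError):
    """A response set does not cover its trial list exactly once."""


class UnsupportedModelError(ValueError):
    """A responder model configuration has no closed-form expectation."""
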