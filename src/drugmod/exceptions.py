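"""Exception hierarchy for drugmod."""


class DrugmodError(Exception):
    """Base class for all drugmod errors."""


class ValidationError(DrugmodError, ValueError):
    """An object violates a declared invariant (duplicate ids, non-finite
    values, empty result after filtering, ...)."""


class ParseError(DrugmodError, ValueError):
    """A file could not be parsed into the expected format."""
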