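"""Exception types shared across the pipeline."""


class RppaClassError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(RppaClassError, ValueError):
    """An input violates a documented contract (shapes, labels, ranges)."""


class ParseError(RppaClassError, ValueError):
    """A file exists but its content cannot be interpreted as a dataset."""
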