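"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented contract (shapes, ranges, invariants)."""


class ParseError(ValueError):
    """A coordinate table or text file could not be parsed.

    Where possible the message names the offending line number.
    """
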