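"""Exception hierarchy for input rejection, parsing, and estimation failures."""


class ActipalError(Exception):
    """Base class for all package errors."""


class InputError(ActipalError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(ActipalError, ValueError):
    """A file does not conform to its declared schema."""


class EstimationError(ActipalError, ValueError):
    """A statistical estimate is undefined for the given data (degenerate design)."""
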