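"""Exception hierarchy shared across the package."""


class EdmrError(Exception):
    """Base class for all package errors."""


class ParseError(EdmrError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(EdmrError, ValueError):
    """Parsed values violate a domain invariant."""


class InsufficientDataError(EdmrError, ValueError):
    """Not enough data to carry out an estimation step."""


class DegenerateMixtureError(EdmrError, RuntimeError):
    """The mixture fit collapsed (vanishing variance or mixing proportion)."""
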