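"""Exception hierarchy used across the package.

Everything derives from :class:`LncsimError` so callers can catch one base.
Parse/validation/parameter errors are also ``ValueError`` subclasses, which
keeps them compatible with generic input-checking code.
"""


class LncsimError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LncsimError, ValueError):
    """A delimited input file is malformed (message names the line)."""


class ValidationError(LncsimError, ValueError):
    """A domain object violates one of its invariants."""


class ParameterError(LncsimError, ValueError):
    """A tunable parameter is outside its documented range."""


class NumericalError(LncsimError, ArithmeticError):
    """A linear solve failed beyond what the jitter can rescue."""
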