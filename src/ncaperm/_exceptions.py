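"""Exception hierarchy for ncaperm."""


class NCAError(Exception):
    """Base class for all ncaperm errors."""


class ValidationError(NCAError, ValueError):
    """Input data or parameters violate a precondition."""


class DegenerateScopeError(NCAError, ValueError):
    """The evaluation rectangle has zero width or zero height.

    Raised when all x values (or all y values) coincide, so the empty-corner
    fraction is undefined.
    """


class SeparationWarning(UserWarning):
    """Logistic fit encountered (quasi-)complete separation; a penalized
    fallback fit was used."""
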