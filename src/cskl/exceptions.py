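"""Exception hierarchy for the cskl package."""


class CsklError(Exception):
    """Base class for all cskl errors."""


class ParseError(CsklError):
    """A delimited-text input could not be parsed."""


class ValidationError(CsklError):
    """An input violates a structural invariant (duplicate IDs, bad shapes...)."""


class AlignmentError(CsklError):
    """Datasets on one platform share no common variables."""


class ParameterError(CsklError):
    """A user-supplied parameter is outside its valid range."""


class DegenerateDataError(CsklError):
    """Data carries no variance to decompose (all eigenvalues zero)."""


class ComparabilityError(CsklError):
    """Two compressed representations are not comparable (different n or alpha)."""


class InsufficientPoolError(CsklError):
    """The pooled sample background is too small for the requested null draw."""
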