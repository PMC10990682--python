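"""Exception hierarchy."""


class CommgemError(Exception):
    """Base class for all errors raised by commgem."""


class FormatError(CommgemError):
    """A file could not be parsed as the declared format."""


class IntegrityError(CommgemError):
    """A model violates a structural invariant (dangling reference etc.)."""


class IdCollisionError(CommgemError):
    """Two distinct identifiers collide after sanitation or prefixing."""


class AmbiguousExchangeError(CommgemError):
    """More than one boundary reaction exists for the same metabolite."""


class BiomassError(CommgemError):
    """No biomass reaction could be identified, or several candidates exist."""


class MatchingError(CommgemError):
    """Boundary-metabolite matching failed (stop-and-inform behaviour)."""


class InfeasibleError(CommgemError):
    """The constraint polytope is empty for the requested computation."""
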