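"""Exception hierarchy for the presigmoid package."""


class PresigmoidError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PresigmoidError):
    """A geometric operation received degenerate or infeasible input
    (collinear plane fit, line parallel to a plane, overlapping discs,
    triangle-inequality violation, unreachable line-of-sight constraint...)."""


class SchemaError(PresigmoidError):
    """A landmark file failed to parse or validate against the published schema.
    The message names the offending field path."""


class ValidationError(PresigmoidError):
    """An in-memory object violates a documented invariant
    (e.g. a cohort table row whose triangle areas do not sum to the total)."""
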