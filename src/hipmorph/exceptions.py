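"""Exception types raised by hipmorph validation and geometry code."""


class HipmorphError(ValueError):
    """Base class for all hipmorph errors."""


class DegenerateGeometryError(HipmorphError):
    """Input geometry does not define the requested construction
    (collinear plane landmarks, coincident head centers, coplanar
    sphere points, ...)."""


class ValidationError(HipmorphError):
    """A domain invariant is violated (rim off the head sphere,
    side/label mismatch, malformed schema, missing stratum, ...)."""


class UndefinedAngleError(HipmorphError):
    """A center-edge angle is undefined because the edge point projects
    onto the femoral-head center in the cutting plane."""


class DegenerateVarianceError(HipmorphError):
    """A statistic is undefined because a group has zero variance."""
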