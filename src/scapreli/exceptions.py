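"""Exception hierarchy shared across the package."""


class ScapreliError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ScapreliError):
    """A landmark/mesh file could not be parsed; names the file and line."""


class ValidationError(ScapreliError):
    """A dataset violates the balanced-design or geometry requirements."""


class DegenerateGeometryError(ScapreliError):
    """Landmark triplet too close to collinear to define a coordinate system."""


class GimbalLockError(ScapreliError):
    """YXZ Euler extraction at a singular configuration (|e2| -> 90 deg)."""


class LandmarkNotFoundError(ScapreliError):
    """A positioning strategy found no vertex satisfying its rule."""
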