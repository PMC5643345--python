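"""Exception types shared across the package."""


class CortivasError(Exception):
    """Base class for package errors."""


class SizingError(CortivasError, ValueError):
    """Requested geometry cannot fit the voxel grid."""


class GeometryError(CortivasError, ValueError):
    """Inconsistent acquisition geometry (pixel/voxel mismatch, bad angles)."""


class MappingError(CortivasError, KeyError):
    """A label code has no entry in the material table."""


class DegenerateInputError(CortivasError, ValueError):
    """Input carries no usable signal (constant volume, no bone, ...)."""


class UndefinedResultError(CortivasError, ZeroDivisionError):
    """A quantity's denominator is empty (no canals, zero bone volume, ...)."""
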