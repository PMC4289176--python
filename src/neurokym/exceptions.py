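"""Exception hierarchy.

Every error raised by the package derives from :class:`NeurokymError` so
pipeline drivers can catch one base class.
"""


class NeurokymError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(NeurokymError):
    """A configuration value violates its invariant (non-positive length, ...)."""


class GeometryError(NeurokymError):
    """Geometry leaves the voxel grid (cell out of field, wall outside grid)."""


class DimensionError(NeurokymError):
    """Image axes cannot be resolved to the canonical (t, c, z, y, x) order."""


class FormatError(NeurokymError):
    """An on-disk table or geometry file violates its schema."""


class MetadataError(NeurokymError):
    """Image metadata is missing or inconsistent (negative voxel size, ...)."""


class SeedError(NeurokymError):
    """A segmentation seed voxel falls below the threshold."""


class AlignmentError(NeurokymError):
    """Two grids that must share a shape do not."""


class InsufficientDataError(NeurokymError):
    """Too few samples for the requested estimate."""


class DegenerateAxisError(NeurokymError):
    """Migration axis endpoints coincide."""
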