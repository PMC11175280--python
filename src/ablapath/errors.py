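"""Exception hierarchy shared across the planning pipeline."""


class AblapathError(Exception):
    """Base class for all package errors."""


class FormatError(AblapathError):
    """Unreadable or unsupported volume file."""


class VoxelTypeError(FormatError):
    """Volume voxels are not an integer type."""


class ConfigurationError(AblapathError):
    """Invalid planning, phantom, or role configuration."""


class BoundsError(AblapathError):
    """Index or world point outside the volume grid."""


class GeometryError(AblapathError):
    """Degenerate geometric input (zero-length segment, ...)."""


class EmptyMaskError(AblapathError):
    """Operation requires a non-empty structure mask.

    For distance fields the caller should treat the distance to an absent
    structure as +infinity at configuration level instead of computing a
    field.
    """


class NoCrossingError(GeometryError):
    """Segment never enters the liver; the capsule angle is undefined."""


class DegenerateNormalError(GeometryError):
    """Smoothed-mask gradient vanishes; no surface normal at this point."""


class StoreError(AblapathError):
    """Planning-record store I/O failure."""


class RecordNotFoundError(StoreError):
    """Requested record id does not exist in the store."""
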