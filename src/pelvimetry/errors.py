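"""Exception hierarchy for the pelvimetry package."""


class PelvimetryError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PelvimetryError):
    """Non-finite or otherwise malformed numeric input."""


class DegenerateGeometryError(PelvimetryError):
    """Geometric construction is undefined (e.g. zero-length ray)."""


class InvalidMetadataError(PelvimetryError):
    """Volume metadata (spacing, affine) is missing or unusable."""


class ConfigError(PelvimetryError):
    """Configuration values violate their invariants."""


class DataError(PelvimetryError):
    """Dataset-level problem: empty set, duplicate ids, no overlap."""


class PlacementError(PelvimetryError):
    """A landmark falls outside the physical extent of its grid."""
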