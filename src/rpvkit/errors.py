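"""Exception hierarchy for rpvkit.

All domain errors derive from :class:`RpvKitError` so callers (and the CLI)
can catch one base class and map it to a nonzero exit code.
"""


class RpvKitError(Exception):
    """Base class for all rpvkit errors."""


class GeometryError(RpvKitError):
    """Inconsistent or invalid image geometry (spacing, orientation, shape)."""


class DataError(RpvKitError):
    """Invalid voxel data, e.g. non-finite values in a loaded CT volume."""


class AlignmentError(RpvKitError):
    """Volume and mask do not share shape/spacing within tolerance."""


class EmptySegmentationError(RpvKitError):
    """A segmentation mask contains no foreground voxels where one is required."""


class SpecError(RpvKitError):
    """A synthetic-data specification is infeasible (e.g. tumor exceeds grid)."""


class ExtractionError(RpvKitError):
    """A feature computation produced a non-finite value; names the feature."""
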