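"""Exception hierarchy for the cortical mapping pipeline."""


class CorticalMapError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CorticalMapError, ValueError):
    """A generator or pipeline parameter violates a stated constraint."""


class SchemaError(CorticalMapError, ValueError):
    """A tabular input is missing required columns or fails validation."""


class FormatError(CorticalMapError, ValueError):
    """A mesh or volume file could not be parsed."""


class SegmentationError(CorticalMapError, RuntimeError):
    """Threshold segmentation could not produce a periosteum/endosteum pair."""


class ResolutionError(CorticalMapError, ValueError):
    """Voxel size too coarse for the requested structure (wall < 3 voxels)."""


class AxisError(CorticalMapError, RuntimeError):
    """The long axis of the shaft could not be determined."""


class CropError(CorticalMapError, RuntimeError):
    """Diaphysis cropping produced an empty or invalid segment."""


class VolumeError(CorticalMapError, RuntimeError):
    """Shaft volume could not be computed from the cropped surface."""


class CutLineError(CorticalMapError, RuntimeError):
    """The unrolling cut line through LM1 is undefined (zero radius)."""


class FitError(CorticalMapError, RuntimeError):
    """Surface smoothing regression failed (e.g. too few points)."""


class GridMismatchError(CorticalMapError, ValueError):
    """Two maps with different grid specifications were combined."""
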