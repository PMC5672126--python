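"""Exception hierarchy for the registration pipeline."""


class CarpRegError(Exception):
    """Base class for all package errors."""


class FormatError(CarpRegError):
    """An input file could not be parsed in the requested format."""


class SeriesError(FormatError):
    """A DICOM series is inconsistent (mixed orientation, spacing or shape)."""


class EmptyMaskError(CarpRegError):
    """A binary volume entering the pipeline contains no foreground voxel."""


class GridMismatchError(CarpRegError):
    """Two volumes that must share a voxel grid have different shapes."""


class SeedError(CarpRegError):
    """The user seed is outside the volume or outside the intensity band."""


class GeometryError(CarpRegError):
    """A synthetic phantom specification is out of grid or degenerate."""


class DegenerateProjectionError(CarpRegError):
    """An eigenvector is (numerically) perpendicular to the rotation plane."""
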