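"""Exception hierarchy.

Every failure mode a caller may want to catch separately gets its own
class; all inherit from :class:`TorsomorphError` so pipeline drivers can
trap per-participant failures with a single except clause.
"""


class TorsomorphError(Exception):
    """Base class for all torsomorph errors."""


class FormatError(TorsomorphError):
    """A file could not be parsed; the message names the offending record."""


class ValidationError(TorsomorphError):
    """Input values violate a documented contract (missing landmark, bad unit...)."""


class GeometryError(TorsomorphError):
    """Degenerate geometry: parallel landmark vectors, zero centroid size..."""


class SparseScanError(TorsomorphError):
    """Too few points survive segmentation to trust the slice profiles."""


class SliceCoverageError(TorsomorphError):
    """A transverse slice band contains fewer raw points than the minimum."""


class ShapeTopologyError(TorsomorphError):
    """A cross-section is not star-shaped about its centroid (empty angular sector)."""


class ResolutionError(TorsomorphError):
    """Angular sampling too coarse for the requested number of Fourier coefficients."""


class DegenerateCohortError(TorsomorphError):
    """Cohort matrix has no variance (or a column does) where variance is required."""


class SingularDesignError(TorsomorphError):
    """Exact collinearity in a regression design matrix."""


class ConfigurationError(TorsomorphError):
    """Inconsistent configuration values (e.g. p_enter >= p_remove)."""
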