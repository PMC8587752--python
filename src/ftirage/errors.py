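"""Exception hierarchy for the ftirage pipeline.

Every stage raises a subclass of :class:`FtirError` so callers can catch
pipeline failures without swallowing programming errors.
"""


class FtirError(Exception):
    """Base class for all ftirage errors."""


class FormatError(FtirError):
    """A file does not conform to the expected text format."""


class ValidationError(FtirError):
    """Metadata or configuration violates a domain constraint."""


class DuplicatePointError(FormatError):
    """The same (sample, wavenumber) pair appears twice in an input file."""


class GridError(FtirError):
    """Wavenumber grids are inconsistent, non-uniform, or out of range."""


class RegionError(FtirError):
    """A requested spectral region does not intersect the grid."""


class SizeError(FtirError):
    """An operation received fewer points than it needs."""


class NormalizationError(FtirError):
    """Area normalization is undefined (non-positive integral)."""


class WindowError(FtirError):
    """A peak-search window contains no grid points."""


class RatioError(FtirError):
    """A band-index denominator is non-positive."""


class ShapeError(FtirError):
    """Matrix dimensions do not match a fitted model."""


class RankError(FtirError):
    """More components requested than the data rank supports."""


class DegenerateDataError(FtirError):
    """The data carry no variance where variance is required."""


class GroupError(FtirError):
    """A required group of samples is empty."""


class CVError(FtirError):
    """Cross-validation is impossible for the given fold count."""
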