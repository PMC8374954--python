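"""Exception hierarchy for the flagellar-kinematics pipeline.

Every error raised deliberately by the package derives from
:class:`FlagkinError`, so callers (and the batch pipeline, which isolates
per-cell failures) can catch one base class.
"""


class FlagkinError(Exception):
    """Base class for all package errors."""


class FormatError(FlagkinError):
    """Input file does not follow the expected dialect (missing columns,
    unknown format tag, forbidden z-coordinate column)."""


class DataError(FlagkinError):
    """File parsed but its content is inconsistent (duplicated frames,
    non-monotone time stamps, NaN values)."""


class InsufficientDataError(DataError):
    """Too few frames, points, or samples for the requested operation."""


class GeometryError(FlagkinError):
    """Degenerate geometry: coincident centerline points, zero-length
    tangents."""


class ParameterError(FlagkinError):
    """Invalid physical or numerical parameter (e.g. wall distance smaller
    than the filament radius, non-increasing region boundaries)."""


class NoOscillationError(FlagkinError):
    """Spectral analysis found no oscillatory content (constant or all-zero
    shape-coefficient series)."""


class DegeneratePhaseError(FlagkinError):
    """Beat phase undefined because the motion is one-dimensional in the
    B1-B2 plane (e.g. B2 identically zero)."""


class InsufficientCyclesError(FlagkinError):
    """Fewer than the minimum number of complete beat cycles in the record."""


class ComparisonError(FlagkinError):
    """Two beat patterns cannot be compared (mismatched phase or arc grids)."""
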