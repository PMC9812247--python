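"""Exception hierarchy for braintx.

All package errors derive from :class:`BraintxError` so callers can catch one
base class; subclasses distinguish bad parameters, misaligned inputs and
degenerate data.
"""


class BraintxError(Exception):
    """Base class for all braintx errors."""


class ParameterError(BraintxError, ValueError):
    """A parameter violates its documented domain."""


class SizingError(ParameterError):
    """Requested structure does not fit the available space (e.g. more
    parcels than voxels)."""


class AlignmentError(BraintxError):
    """Two spatial objects do not share geometry or unit identifiers."""


class FormatError(BraintxError):
    """A file could not be parsed as the expected format."""


class DimensionalityError(FormatError):
    """A volume file does not contain a 3-D payload."""


class GeometryError(BraintxError):
    """Spatial coordinates are degenerate (e.g. all units co-located)."""


class EmptyProfileError(BraintxError):
    """Profile extraction produced no spatial units."""


class UndefinedCorrelationError(BraintxError):
    """Correlation is undefined (constant input vector)."""


class DegenerateSetError(ParameterError):
    """A gene set is empty or spans the whole universe."""


class DegenerateDatabaseError(BraintxError):
    """A motif database has no score dispersion."""
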