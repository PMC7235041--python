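"""Exception hierarchy for the infonets pipeline.

Every stage raises a subclass of :class:`InfonetsError` so callers can
distinguish configuration problems (exit code 2) from data problems
(exit code 3).
"""


class InfonetsError(Exception):
    """Base class for all infonets errors."""


class InvalidParameterError(InfonetsError, ValueError):
    """A parameter is outside its documented domain."""


class ConfigError(InfonetsError, ValueError):
    """A study or analysis configuration is internally inconsistent."""


class DataError(InfonetsError, ValueError):
    """Input data violates a precondition (shape, coverage, compatibility)."""


class DegeneratePatternError(DataError):
    """An item's feature vector has zero variance; no correlation is defined."""


class DegenerateDMError(DataError):
    """A dissimilarity vector is constant; normalization is undefined."""


class DegenerateSampleError(DataError):
    """A sample has zero variance; the t statistic is undefined."""


class InsufficientGroupError(DataError):
    """Fewer subjects than the operation requires."""


class EmptyRegionError(DataError):
    """A region-label class contains no nodes."""


class IncompatibleMeshError(DataError):
    """Two surface objects do not share the same mesh."""
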