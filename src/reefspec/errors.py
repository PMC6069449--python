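"""Exception hierarchy shared across the pipeline."""


class ReefspecError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ReefspecError, ValueError):
    """A parameter violates an operation's preconditions."""


class ShapeError(ReefspecError, ValueError):
    """Array shapes or wavelength grids do not line up."""


class CorruptFileError(ReefspecError, OSError):
    """Header and binary payload of a cube are inconsistent."""


class UnsupportedFormatError(ReefspecError, ValueError):
    """Requested or encountered file dialect is not supported."""


class ValidationError(ReefspecError, ValueError):
    """A table record violates its schema (e.g. bleaching level outside 1-6)."""


class EmptyDomainError(ReefspecError, ValueError):
    """An operation was asked to sample from an empty domain."""


class InvalidReferenceError(ReefspecError, ValueError):
    """A white-reference spectrum is unusable (zero or negative bands)."""


class CalibrationError(ReefspecError, ValueError):
    """Depth calibration lacks usable points or is degenerate."""


class OutOfRangeError(ReefspecError, ValueError):
    """A target wavelength falls outside the grid's span."""


class CoverageError(ReefspecError, ValueError):
    """The cube's wavelength grid does not cover the requested range."""


class DegenerateTrainingError(ReefspecError, ValueError):
    """Classifier training set has fewer than two classes."""


class UndefinedDenominatorError(ReefspecError, ZeroDivisionError):
    """A ratio statistic was requested with a zero denominator."""
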