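"""Exception hierarchy shared across the package."""


class SolePostureError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SolePostureError, ValueError):
    """A file does not follow the documented dialect (e.g. missing column)."""


class ValidationError(SolePostureError, ValueError):
    """Data violate a recording invariant (negative force, bad timestamps...)."""


class ParameterError(SolePostureError, ValueError):
    """A caller-supplied parameter is out of its admissible range."""


class EmptyTrajectoryError(SolePostureError, RuntimeError):
    """Every frame of a recording fell below the force threshold."""


class SegmentationError(SolePostureError, RuntimeError):
    """No frames satisfy the single-support stance conditions."""


class RenderingError(SolePostureError, RuntimeError):
    """A target COP frame could not be realised by non-negative zone forces."""


class CohortError(SolePostureError, ValueError):
    """A requested synthetic cohort is too small or inconsistent."""


class StratificationError(SolePostureError, RuntimeError):
    """A cross-validation fold ended up with a single class in its test set."""
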