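"""Exception hierarchy for the motioncpm pipeline.

Every error raised by the package derives from :class:`MotionCPMError`,
so callers can catch pipeline failures without catching programming errors.
"""


class MotionCPMError(Exception):
    """Base class for all motioncpm errors."""


class FormatError(MotionCPMError):
    """A file does not conform to the expected on-disk format."""


class ParseError(FormatError):
    """A cell or token could not be parsed; carries the offending row."""


class ValidationError(MotionCPMError):
    """Input values violate a documented precondition (non-finite, empty...)."""


class DimensionError(MotionCPMError):
    """Shapes or node sets of two objects do not line up."""


class DegenerateDataError(MotionCPMError):
    """Data are degenerate for the requested operation (constant column,
    zero-variance node, rank-deficient regressors)."""


class FitError(MotionCPMError):
    """A model fit could not be carried out (e.g. collinear strengths)."""


class InvalidResultError(MotionCPMError):
    """A result is undefined (constant scores, all folds degenerate)."""


class GenerationError(MotionCPMError):
    """Synthetic-data generation failed (e.g. covariance projection)."""


class PartitionError(MotionCPMError):
    """A network partition does not cover the requested nodes/labels."""
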