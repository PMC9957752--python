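"""Exception and warning hierarchy.

Every failure mode the pipeline can surface has a dedicated class so callers
can distinguish bad arguments from bad data from model inconsistencies.
"""


class HepatodeconError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HepatodeconError, ValueError):
    """A parameter violates its documented bounds."""


class DataError(HepatodeconError):
    """Input data violate an invariant (e.g. non-positive transcript length)."""


class FormatError(HepatodeconError):
    """A file does not parse as the declared format."""


class MarkerInvalidError(HepatodeconError):
    """A marker gene is absent or silent in its own cell-type profile."""


class MarkerDeficitError(HepatodeconError):
    """Fewer cell-type-exclusive genes than the required minimum."""


class EstimationError(HepatodeconError):
    """No valid marker survived; a cell fraction cannot be estimated."""


class ApportionmentError(HepatodeconError):
    """A gene cannot be apportioned (absent or zero in the tissue profile)."""


class InvalidDesignError(HepatodeconError):
    """A differential-expression design is degenerate (a group with <2 samples)."""


class EmptySignatureError(HepatodeconError):
    """No gene passed the signature thresholds."""


class ScoringError(HepatodeconError):
    """No signature gene overlaps the cohort matrix."""


class SplitError(HepatodeconError):
    """A train/test split left a class absent from one side."""


class UndefinedAUCError(HepatodeconError):
    """ROC requested with a single-class label vector."""


class ContainmentError(HepatodeconError):
    """A gene set is not contained in the declared universe."""


class UndefinedCorrelationError(HepatodeconError):
    """Correlation requested on a zero-variance vector."""


class HepatodeconWarning(UserWarning):
    """Base class for package warnings."""


class ClippingWarning(HepatodeconWarning):
    """An estimate fell outside [0, 1] and was clipped."""


class InconsistencyWarning(HepatodeconWarning):
    """Estimates are jointly inconsistent with the mixture model (e.g. NPC > 1)."""


class SeparationWarning(HepatodeconWarning):
    """Perfect separation detected during a logistic fit."""


class NormalizationWarning(HepatodeconWarning):
    """Sample library sizes differ enough to distort unnormalized scoring."""
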