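"""Exception hierarchy for eegspike.

All package-specific failures derive from :class:`EegError` so callers can
catch one base class at pipeline level while tests target precise subclasses.
"""


class EegError(Exception):
    """Base class for all eegspike errors."""


class SegmentFormatError(EegError):
    """A segment file could not be parsed (message names the offending line)."""


class DegenerateSignalError(EegError):
    """Operation undefined on a constant (zero-variance) signal."""


class DegenerateClassError(EegError):
    """A class has too few members for the requested statistic."""


class SegmentLengthError(EegError):
    """The signal is too short for the requested operation."""


class DecompositionDepthError(SegmentLengthError):
    """Signal too short for the requested wavelet decomposition depth."""


class SubsegmentError(EegError):
    """Invalid Welch sub-segment count."""


class LagError(EegError):
    """Delay-embedding lag incompatible with the signal length."""


class EstimationError(EegError):
    """A nonlinear estimator has no valid pairs/points to work with."""


class FitError(EegError):
    """Too few points in the requested regression window."""


class ConditioningError(EegError):
    """A matrix is singular beyond the ridge repair threshold."""


class StratificationError(EegError):
    """A class is smaller than the number of cross-validation folds."""


class LabelError(EegError):
    """A label outside the expected class set was encountered."""
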