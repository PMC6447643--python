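"""Exception hierarchy for the fpaperf pipeline.

Every error raised by this package derives from :class:`FpaError`, so callers
can catch a single base class at pipeline boundaries.
"""


class FpaError(Exception):
    """Base class for all fpaperf errors."""


class InvalidParameterError(FpaError, ValueError):
    """A configuration or physical parameter is out of its valid domain."""


class DimensionError(FpaError, ValueError):
    """Array shapes or masks do not agree with the phantom grid."""


class DegenerateCurveError(FpaError, ValueError):
    """A time-density curve is too flat to carry bolus information."""


class FitFailureError(FpaError, RuntimeError):
    """Nonlinear least squares failed to converge after restarts."""


class IllPosedLandmarkError(FpaError, ValueError):
    """The base landmark is undefined (shape parameter b <= 2)."""


class InsufficientDataError(FpaError, ValueError):
    """Not enough points/groups for the requested statistic."""


class DegenerateRegressorError(InsufficientDataError):
    """The regressor is constant; slope is unidentifiable."""


class NoTriggerError(FpaError, RuntimeError):
    """Monitoring curve never reached the trigger threshold."""


class AcquisitionWindowError(FpaError, RuntimeError):
    """The gated-scan window ended before a required volume scan."""


class NonPhysiologicalInputError(FpaError, ValueError):
    """Arterial input is non-positive; perfusion is undefined."""


class InvalidEnhancementError(FpaError, ValueError):
    """Mean myocardial enhancement change is not positive."""


class DegenerateTestError(FpaError, ValueError):
    """Paired differences have zero variance; t statistic undefined."""


class DiameterRangeError(FpaError, ValueError):
    """Effective diameter outside the validity range of the SSDE table."""
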