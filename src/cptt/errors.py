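"""Exception hierarchy.

All package-specific failures derive from :class:`CPTTError` so callers
(and the CLI) can catch one base class.
"""


class CPTTError(Exception):
    """Base class for all errors raised by this package."""


class ScheduleError(CPTTError):
    """Invalid frame-schedule specification (non-positive count/duration/delay)."""


class GeometryError(CPTTError):
    """Image / mask grids are incompatible, or VOIs overlap or fall outside the volume."""


class EmptyVOIError(CPTTError):
    """A volume of interest contains no voxels."""


class FormatError(CPTTError):
    """A file on disk does not match the expected format (dimensionality, sidecar)."""


class ParameterError(CPTTError):
    """A simulation or model parameter is outside its admissible range."""


class CoverageError(CPTTError):
    """The frame schedule extends beyond the support of a continuous curve."""


class NoPeakError(CPTTError):
    """A time-activity curve has no identifiable first-pass peak (flat, all-zero or monotone)."""


class PeakOrderError(CPTTError):
    """The left-ventricular peak precedes the right-ventricular peak.

    Physiologically impossible for a venous bolus; usually means the VOI
    labels are swapped.
    """


class DegenerateDesignError(CPTTError):
    """Regression design matrix is rank deficient (constant predictor)."""


class InsufficientDataError(CPTTError):
    """Too few complete cases for the requested analysis."""
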