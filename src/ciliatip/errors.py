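"""Exception hierarchy for the ciliatip pipeline.

Every stage raises a subclass of :class:`CiliaTipError` so that pipeline
drivers can report the failing stage by exception type.
"""


class CiliaTipError(Exception):
    """Base class for all ciliatip errors."""


class ParameterError(CiliaTipError, ValueError):
    """Invalid or inconsistent parameter values."""


class GeometryError(CiliaTipError):
    """Requested imaging geometry cannot contain the trajectory."""


class FormatError(CiliaTipError, ValueError):
    """Malformed on-disk data (CSV/JSON), with the offending location named."""


class LocalizationError(CiliaTipError):
    """A single-frame spot fit failed (flagged per frame, not fatal)."""


class TrackingQualityError(CiliaTipError):
    """Too many frames failed localization to trust the track."""


class SegmentationError(CiliaTipError):
    """No beat cycles could be delimited in the trajectory."""


class FrequencyUndeterminedError(CiliaTipError):
    """No periodogram peak rises above the noise floor."""


class UndefinedGapError(CiliaTipError):
    """Effective and recovery strokes share no x-range; z-gap undefined."""


class FitDegenerateError(CiliaTipError):
    """Sphere fit has insufficient 3-D extent even for the constrained fall-back."""


class ModelDomainError(CiliaTipError):
    """Hydrodynamic formula evaluated outside its domain (e.g. L <= 2a)."""


class AmbiguousPlaneWarning(UserWarning):
    """Lateral motion nearly isotropic; beating-plane alignment is uncertain."""


class LowAsymmetryWarning(UserWarning):
    """Effective/recovery mean speeds nearly equal; tie broken by convention."""
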