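"""Exception types shared across the package."""


class OvigaitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OvigaitError, ValueError):
    """A file does not conform to the expected recording/manifest dialect."""


class ValidationError(OvigaitError, ValueError):
    """An input value violates a documented precondition."""


class ResolutionError(OvigaitError, ValueError):
    """A requested waveform cannot be represented at the sampling rate."""


class CalibrationError(OvigaitError, ValueError):
    """A template calibration target is outside the achievable family range."""


class InsufficientDataError(OvigaitError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDesignError(OvigaitError, ValueError):
    """Regression design matrix is singular (e.g. constant predictor)."""


class UndefinedAsymmetryError(OvigaitError, ValueError):
    """Asymmetry index is undefined (both limb values are zero)."""
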