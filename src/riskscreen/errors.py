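"""Exception types shared across the package."""


class RiskScreenError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(RiskScreenError, ValueError):
    """A scenario or strategy parameter is outside its documented range."""


class InfeasibleTargetError(RiskScreenError, RuntimeError):
    """The target detection rate cannot be reached even at full coverage."""


class CalibrationAnomalyError(RiskScreenError, RuntimeError):
    """Threshold calibration detected an inconsistent bracket."""
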