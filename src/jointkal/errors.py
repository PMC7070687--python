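"""Exception hierarchy for jointkal."""


class JointkalError(Exception):
    """Base class for all jointkal errors."""


class ValidationError(JointkalError):
    """Input data violates a structural invariant (gaps, duplicates, cycles...)."""


class ParseError(JointkalError):
    """A file could not be parsed; the message names the offending line."""


class EstimationError(JointkalError):
    """A quantity (e.g. a bone length) could not be estimated from the data."""


class CalibrationError(JointkalError):
    """Threshold calibration is impossible (e.g. no manually labelled errors)."""


class ConfigurationError(JointkalError):
    """Pipeline configuration is incomplete or inconsistent."""


class FilterNumericalError(JointkalError):
    """A Kalman step failed numerically (singular innovation covariance...)."""


class DegenerateDirectionError(JointkalError):
    """Sphere projection has no defined direction (estimate coincides with parent)."""


class SingularGeometryError(JointkalError):
    """Measurement geometry is singular (e.g. z = 0 for the bearing channel)."""
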