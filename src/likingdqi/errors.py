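"""Exception types raised across the package."""


class LikingDQIError(Exception):
    """Base class for package errors."""


class MissingGroupError(LikingDQIError):
    """A food group has too few non-missing item ratings to score."""


class UndefinedAlphaError(LikingDQIError):
    """Cronbach alpha is undefined (zero total variance)."""


class RankDeficiencyError(LikingDQIError):
    """Unpenalized least squares requested on a rank-deficient design."""


class ConstantColumnError(LikingDQIError):
    """A constant column makes a correlation-based analysis undefined."""


class ConvergenceError(LikingDQIError):
    """An iterative procedure failed to converge."""


class ConfigurationError(LikingDQIError):
    """Inconsistent or infeasible configuration values."""


class OrientationError(LikingDQIError):
    """A score's healthy/unhealthy orientation cannot be determined."""
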