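"""Exception hierarchy shared across the package."""


class ICEDError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ICEDError):
    """Invalid generator or pipeline configuration (negative variance, bad range, ...)."""


class SchemaError(ICEDError):
    """A dataset violates the documented tidy schema (missing columns, duplicate keys, NaNs)."""


class InsufficientDataError(ICEDError):
    """Fewer complete cases than the minimum the estimator requires."""


class NotPositiveSemiDefiniteError(ICEDError):
    """A covariance summary is not a valid (PSD) covariance matrix."""


class ConvergenceError(ICEDError):
    """The ML optimizer failed to converge and no flagged fallback was requested."""
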