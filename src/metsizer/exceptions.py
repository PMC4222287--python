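"""Exception and warning types raised across the package."""


class MetsizerError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(MetsizerError, ValueError):
    """Array shapes or latent dimensions are inconsistent."""


class DomainError(MetsizerError, ValueError):
    """A parameter is outside its mathematically valid domain."""


class ConfigError(MetsizerError, ValueError):
    """A run configuration is internally inconsistent."""


class DegenerateDataError(MetsizerError, ValueError):
    """The data carry no usable variability (e.g. zero variance everywhere)."""


class DegenerateStatisticError(MetsizerError, ValueError):
    """A test statistic is 0/0-undefined for one or more bins.

    Carries the offending bin indices in ``bins``.
    """

    def __init__(self, message: str, bins=None):
        super().__init__(message)
        self.bins = list(bins) if bins is not None else []


class ConvergenceError(MetsizerError, RuntimeError):
    """Iterative fitting failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, loglik_trace=None):
        super().__init__(message)
        self.loglik_trace = list(loglik_trace) if loglik_trace is not None else []


class LabelError(MetsizerError, ValueError):
    """Group labels do not define exactly two levels."""


class PilotParseError(MetsizerError, ValueError):
    """A pilot-data file could not be parsed into a rectangular numeric table."""


class CollinearityWarning(UserWarning):
    """Covariate design matrix is rank deficient."""
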