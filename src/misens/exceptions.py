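"""Exception types shared across the package."""


class MisensError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MisensError):
    """A configuration object or run-config file is invalid.

    The message names the offending field.
    """


class InsufficientDataError(MisensError):
    """Too few observations to fit a subject-level trend."""


class NotImputableError(MisensError):
    """A subject lacks the minimal longitudinal history required for imputation."""


class UnimputableVariableError(MisensError):
    """A target variable has no observed cases to fit an imputation model on."""


class NonMonotoneError(MisensError):
    """A block passed to the monotone imputation path is not monotone."""


class NonConvergenceError(MisensError):
    """The chained-equation sampler failed its stationarity check."""


class PredictorReductionError(MisensError):
    """Collinearity reduction removed every predictor for a target."""


class TrialError(MisensError):
    """A sensitivity simulation trial cannot be carried out as configured."""
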