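"""Exception hierarchy for stratmr."""


class StratMRError(Exception):
    """Base class for all stratmr errors."""


class InvalidParameterError(StratMRError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class CalibrationError(StratMRError):
    """Intercept calibration failed (e.g. target rate of 0 or 1)."""


class HarmonizationError(StratMRError):
    """Allele pair in the cohort is incompatible with the weight table."""


class WeakInstrumentError(StratMRError):
    """Instrument-exposure association is zero; ratio estimate undefined."""


class SeparationError(StratMRError):
    """Logistic regression suffered (quasi-)complete separation."""


class StratificationError(StratMRError):
    """Stratification preconditions violated (e.g. N < K^2)."""


class MetaRegressionError(StratMRError):
    """LACE meta-regression cannot be fit (too few strata, degenerate means)."""


class FitError(StratMRError):
    """A regression fit failed irrecoverably."""
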