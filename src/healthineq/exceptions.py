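"""Exception hierarchy shared across the package."""


class HealthineqError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HealthineqError):
    """An invalid generator or study configuration; the message names the field."""


class AlignmentError(HealthineqError):
    """Input vectors are not aligned (length mismatch or mismatched index)."""


class UndefinedIndexError(HealthineqError):
    """The requested index is undefined for this sample (e.g. zero-mean outcome)."""


class SeparationError(HealthineqError):
    """Probit likelihood is degenerate: a covariate perfectly separates the outcome."""


class ConvergenceError(HealthineqError):
    """Iterative fit failed to converge; message carries the iteration trace."""
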