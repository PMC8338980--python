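"""Exception types shared across the package."""


class GinScreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GinScreenError, ValueError):
    """A cohort table violates the declared schema (range, missingness, columns)."""


class InvalidSpecError(GinScreenError, ValueError):
    """A generator or model specification violates its invariants."""


class CalibrationError(GinScreenError, RuntimeError):
    """Intercept calibration could not reach the requested prevalence."""


class VocabularyError(GinScreenError, ValueError):
    """Node vocabulary mismatch or invalid restriction."""


class ResamplingError(GinScreenError, ValueError):
    """Resampling preconditions violated (e.g. no positives, too few minority rows)."""


class PipelineError(GinScreenError, RuntimeError):
    """A workflow stage was invoked without its upstream artifacts."""
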