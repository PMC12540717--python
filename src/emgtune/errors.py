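"""Exception hierarchy for the emgtune pipeline."""


class EmgtuneError(Exception):
    """Base class for all emgtune errors."""


class SignalParseError(EmgtuneError):
    """A signal file could not be parsed (missing, non-numeric, ragged)."""


class SchemaError(EmgtuneError):
    """A feature table or manifest does not match the expected schema."""


class FilterDesignError(EmgtuneError):
    """Filter design parameters are infeasible (e.g. band edge at/above Nyquist)."""


class ConfigurationError(EmgtuneError):
    """Mutually inconsistent or out-of-range configuration values."""


class SegmentationError(EmgtuneError):
    """A record is too short to yield a single analysis window."""


class FeatureError(EmgtuneError):
    """A feature is undefined for the given window or spectrum."""


class SplitError(EmgtuneError):
    """A train/test partition cannot be formed as requested."""


class RegistryError(EmgtuneError):
    """Unknown classifier backend name."""


class ValidationError(EmgtuneError):
    """A hyperparameter value lies outside its declared dimension."""


class DegenerateVarianceError(EmgtuneError):
    """Paired differences have zero sample variance; the t statistic is undefined."""


class OptimizationError(EmgtuneError):
    """Invalid optimizer state or budget."""
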