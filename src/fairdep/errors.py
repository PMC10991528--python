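"""Exception hierarchy for fairdep."""


class FairdepError(Exception):
    """Base class for all fairdep errors."""


class SchemaError(FairdepError):
    """A declared column is missing or a schema is malformed."""


class CohortValidationError(FairdepError):
    """Cohort contents violate an invariant (e.g. non-binary labels)."""


class ConfigError(FairdepError):
    """A synthetic-data or scenario configuration is invalid."""


class UndefinedMetricError(FairdepError):
    """A metric is requested on data where it is mathematically undefined
    (single-class labels, fewer than two groups with defined rates, ...)."""


class UnsupportedFeatureError(FairdepError):
    """An operation was asked to act on a feature type it does not support
    (e.g. quantile repair of an unordered categorical)."""


class ScenarioError(FairdepError):
    """A cross-validation scenario could not be evaluated."""
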