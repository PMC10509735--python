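"""Exception taxonomy used across the pipeline."""

__all__ = [
    "StackMilError", "ConfigurationError", "ValidationError", "DataError",
    "RegistrationError", "MetricError",
]


class StackMilError(Exception):
    """Base class for package errors."""


class ConfigurationError(StackMilError):
    """Invalid or inconsistent configuration values."""


class ValidationError(StackMilError):
    """Malformed inputs (tables, pairings, annotations)."""


class DataError(StackMilError):
    """Unusable data conditions (empty corpus, single-class training set)."""


class RegistrationError(StackMilError):
    """Stack registration could not be estimated."""


class MetricError(StackMilError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""
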