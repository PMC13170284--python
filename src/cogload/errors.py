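"""Exception types shared across the package."""


class CogloadError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CogloadError):
    """A simulation or analysis configuration value is invalid.

    The message names the offending field.
    """


class SpecificationError(CogloadError):
    """A model specification is inconsistent with the data or with itself."""


class OrderingError(CogloadError):
    """An event stream violates the required chronological ordering."""


class MissingDataError(CogloadError):
    """A required input variable is absent; the message names the variable."""


class DomainError(CogloadError):
    """An input value lies outside the admissible domain."""


class UndefinedMetricError(CogloadError):
    """A cognitive-load metric is undefined (e.g. zero merged events)."""
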