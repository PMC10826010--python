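"""Exception hierarchy shared across the package."""


class STSGError(Exception):
    """Base class for all package errors."""


class SchemaError(STSGError):
    """A table does not match its declared variable schema."""


class AlignmentError(STSGError):
    """Static and series components disagree on the subject set or order."""


class UnrecoverableSubjectError(STSGError):
    """A retained subject has a variable with no valid sample at all."""


class UnknownCategoryError(STSGError):
    """A categorical value lies outside the schema's declared categories."""


class CapacityError(STSGError):
    """More synthetic metadata rows than available series in the pool."""


class ConfigurationError(STSGError):
    """Invalid run/model configuration."""


class DivergenceError(STSGError):
    """Non-finite loss encountered during adversarial training."""


class InsufficientDataError(STSGError):
    """Too few subjects/records for the requested statistic."""
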