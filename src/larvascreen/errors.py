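"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A delimited input table is missing required columns."""


class MalformedTrackError(ValueError):
    """A trajectory violates the constant-frame-interval contract."""


class DimensionError(ValueError):
    """Companion tables disagree in shape or labels."""


class ConfigurationError(ValueError):
    """A schedule, arm, effect library or pipeline config is inconsistent."""


class InsufficientDataError(ValueError):
    """Too few frames or samples for the requested statistic."""


class UndefinedResultError(ValueError):
    """The requested quantity has no defined value for this input."""


class UnknownLabelError(KeyError):
    """A treatment, behavior or drug label is not present."""
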