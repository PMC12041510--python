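"""Exception types shared across the pipeline."""


class VitalcastError(Exception):
    """Base class for all package errors."""


class ParameterError(VitalcastError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class ConfigurationError(VitalcastError, ValueError):
    """A missing or inconsistent configuration item."""


class SchemaError(VitalcastError, ValueError):
    """A variable-role schema refers to variables the data does not have."""


class ShapeError(VitalcastError, ValueError):
    """Array inputs whose shapes do not match the declared roles."""


class DataError(VitalcastError, ValueError):
    """Empty or otherwise unusable data where content is required."""


class InsufficientDataError(VitalcastError, ValueError):
    """Too few real observations to compute the requested statistic."""
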