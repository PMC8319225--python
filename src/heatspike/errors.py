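"""Exception hierarchy shared across the pipeline stages."""


class HeatspikeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(HeatspikeError, ValueError):
    """A function argument violates its contract."""


class SchemaError(HeatspikeError):
    """A table is missing required columns or has misaligned shapes."""


class ConfigurationError(HeatspikeError):
    """Inconsistent configuration (missing calendar year, unmapped city, ...)."""


class GapError(HeatspikeError):
    """An hourly series has missing hours.

    Attributes
    ----------
    missing : list
        The missing (city_id, timestamp) pairs, possibly truncated.
    """

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = list(missing or [])


class RecordValidationError(HeatspikeError):
    """Record-level validation failure (e.g. an unknown severity label)."""

    def __init__(self, message, bad_records=None):
        super().__init__(message)
        self.bad_records = bad_records


class FitError(HeatspikeError):
    """A model fit failed (singular design, single-class labels, ...)."""


class GridSearchError(HeatspikeError):
    """Every grid point of a hyperparameter search failed."""
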