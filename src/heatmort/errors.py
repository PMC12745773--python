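"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (config 2, data 3, numerical 4).
"""


class HeatmortError(Exception):
    """Base class for all package errors."""


class ConfigError(HeatmortError):
    """Invalid configuration or model specification."""


class DataError(HeatmortError):
    """Input data violates the panel contract."""


class SchemaError(DataError):
    """A required column is missing or unparseable."""


class IntegrityError(DataError):
    """Duplicate keys, gaps, or invariant violations in otherwise parseable data."""


class NumericalError(HeatmortError):
    """Estimation failed to converge or produced a degenerate system."""
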