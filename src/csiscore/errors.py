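"""Exception hierarchy.

Validation problems (bad measurements, malformed files, bad configuration)
are distinguished from degenerate-statistics problems (single-class cohorts,
zero rank variance) because the command line maps them to different exit
codes: 2 for validation, 3 for degenerate statistics.
"""


class CsiError(Exception):
    """Base class for all package errors."""


class MeasurementError(CsiError):
    """A lesion measurement violates its physical constraints."""


class SchemaError(CsiError):
    """An input table does not conform to the expected schema."""


class ConfigError(CsiError):
    """Invalid configuration values."""


class DegenerateDataError(CsiError):
    """A statistic is undefined on the given data (single class, all ties...)."""
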