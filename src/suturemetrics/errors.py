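"""Exception hierarchy shared across the pipeline."""


class SutureMetricsError(Exception):
    """Base class for all package errors."""


class InputError(SutureMetricsError, ValueError):
    """Malformed or out-of-contract input data."""


class CalibrationError(SutureMetricsError):
    """Checkerboard geometry too degenerate to estimate a scale."""


class UnitError(SutureMetricsError):
    """Quantities combined across incompatible units (mm vs px)."""


class ConfigError(SutureMetricsError):
    """Invalid configuration value or unknown option label."""
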