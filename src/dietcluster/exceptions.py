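"""Exception hierarchy used across the package."""


class DietClusterError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DietClusterError):
    """A configuration value is invalid; the message names the field."""


class InputError(DietClusterError):
    """Malformed or inconsistent input data."""


class InsufficientDataError(DietClusterError):
    """Too little data to compute the requested quantity."""


class DegenerateExposureError(DietClusterError):
    """An exposure has too few distinct values to form quartiles."""


class FitError(DietClusterError):
    """A regression model failed to converge or could not be fit."""
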