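"""Exception hierarchy shared across the package.

Configuration / schema problems map to CLI exit code 2, data problems to
exit code 3 (see :mod:`paccquant.cli`).
"""


class PaccQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PaccQuantError):
    """A configuration value is invalid or missing; names the offending field."""

    exit_code = 2


class SchemaError(ConfigurationError):
    """An input table does not match the declared column mapping."""


class DegenerateParameterError(ConfigurationError):
    """A parameter combination makes the model undefined (e.g. Poisson ratio = 1)."""


class DataError(PaccQuantError):
    """Input data is structurally valid but unusable for the requested analysis."""

    exit_code = 3


class InsufficientDataError(DataError):
    """Fewer samples than the estimator requires."""


class UnmeasurableSignalError(DataError):
    """Signal amplitude below the declared noise floor; the quantity is unmeasurable."""
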