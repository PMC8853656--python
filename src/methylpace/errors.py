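"""Exception hierarchy shared across the toolkit.

Exit codes follow the CLI contract: 2 usage/configuration, 3 data/validation,
4 numerical failure.
"""


class MethylPaceError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class ConfigurationError(MethylPaceError):
    """Invalid configuration or argument values."""

    exit_code = 2


class DomainError(ConfigurationError):
    """Argument outside its mathematical domain (e.g. ICC not in (0, 1])."""


class DataError(MethylPaceError):
    """Input data violates a precondition."""

    exit_code = 3


class SchemaError(DataError):
    """File does not match the expected schema."""


class AlignmentError(DataError):
    """Sample or probe identifiers of two inputs do not line up."""


class DegenerateDataError(DataError):
    """Data carry no information for the requested estimate (zero variance)."""


class IntegrityError(DataError):
    """A model artifact is internally inconsistent."""


class FormatError(DataError):
    """A model artifact has an unknown or incompatible format version."""


class NumericalError(MethylPaceError):
    """Numerical failure during estimation."""

    exit_code = 4


class FitError(NumericalError):
    """Model fitting failed to produce a usable estimate."""


class ScalingError(NumericalError):
    """Composite scaling is undefined (non-positive cohort mean)."""
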