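"""Exception hierarchy for gxescreen.

Every error raised deliberately by the package derives from
:class:`GxeError`, so callers can catch package failures without also
swallowing programming errors.
"""


class GxeError(Exception):
    """Base class for all gxescreen errors."""


class SchemaError(GxeError):
    """An input table is missing a mandatory column or has a bad mapping."""


class ValidationError(GxeError):
    """A cohort table violates a data-model invariant."""


class ParameterError(GxeError, ValueError):
    """A numeric parameter is outside its admissible range."""


class ConfigurationError(GxeError):
    """A run or simulation configuration references unknown variables."""


class DegenerateTableError(GxeError):
    """A contingency table has a zero margin or too few levels."""


class NonEstimableError(GxeError):
    """An odds ratio or model cannot be estimated from the data given."""


class SeparationError(NonEstimableError):
    """Logistic fit diverged: outcome perfectly separated by the design."""


class CollinearityError(GxeError):
    """Design matrix is rank deficient; names the offending terms."""


class UndefinedStatisticError(GxeError):
    """A test statistic is undefined for the given input (e.g. zero variance)."""
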