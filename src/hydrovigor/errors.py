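"""Exception hierarchy for hydrovigor.

All package-specific failures derive from :class:`HydrovigorError` so callers
can catch one base class at pipeline boundaries.
"""


class HydrovigorError(Exception):
    """Base class for all hydrovigor errors."""


class SchemaError(HydrovigorError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(HydrovigorError):
    """A data record violates an invariant (sign convention, monotonicity, ...)."""


class InsufficientDataError(HydrovigorError):
    """Too few usable observations to attempt an estimate."""


class IdentifiabilityError(HydrovigorError):
    """The design cannot identify the model (e.g. a single water potential)."""


class FitFailureError(HydrovigorError):
    """The estimation procedure produced a result inconsistent with the model."""


class UndefinedStatisticError(HydrovigorError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
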