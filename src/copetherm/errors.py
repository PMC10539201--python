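"""Exception hierarchy for copetherm.

All package-specific failures derive from :class:`CopethermError` so callers
can catch one base class; subclasses distinguish parameter validation, data
sufficiency and schema problems.
"""


class CopethermError(Exception):
    """Base class for all copetherm errors."""


class ParameterError(CopethermError, ValueError):
    """A model or truth parameter violates its invariants."""


class InsufficientDataError(CopethermError, ValueError):
    """Too few distinct temperatures (or points) to attempt a fit."""


class DegenerateDataError(CopethermError, ValueError):
    """Data carry no information about the quantity being fitted.

    Raised e.g. when every individual survived (or died) so the mortality
    transition was never observed.
    """


class MissingCIError(CopethermError, ValueError):
    """A confidence interval required for a comparison is absent."""


class SchemaError(CopethermError, ValueError):
    """An input table does not match its declared schema."""


class EmptyInputError(CopethermError, ValueError):
    """An input file parsed to zero rows."""
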