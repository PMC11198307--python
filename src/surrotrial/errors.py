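"""Exception hierarchy shared across the analysis stages."""


class SurrotrialError(Exception):
    """Base class for all package errors."""


class SchemaError(SurrotrialError):
    """The input table does not match the documented CSV schema."""


class ValidationError(SurrotrialError):
    """A record violates a data-model invariant (names the offending id)."""


class InsufficientPairsError(SurrotrialError):
    """Too few informative comparisons to fit the requested analysis."""


class DegenerateDesignError(SurrotrialError):
    """The regression design is degenerate (e.g. all surrogate effects equal)."""


class UndefinedStatisticError(SurrotrialError):
    """A statistic is undefined on this input (e.g. zero total sum of squares)."""
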