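"""Exception hierarchy for the screening pipeline."""


class PqtlScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(PqtlScreenError, ValueError):
    """Input violates a documented precondition."""


class SimulationError(PqtlScreenError, RuntimeError):
    """The cohort simulator could not satisfy a sampling quota."""


class SeparationError(PqtlScreenError, RuntimeError):
    """Perfect separation detected during logistic-regression fitting."""


class UndefinedLDError(PqtlScreenError, ValueError):
    """LD requested for a monomorphic locus (correlation undefined)."""


class ParseError(PqtlScreenError, ValueError):
    """A genotype or table file failed to parse."""
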