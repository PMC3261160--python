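"""Exception hierarchy for the model pipeline."""


class RenalCEAError(Exception):
    """Base class for all package errors."""


class ValidationError(RenalCEAError, ValueError):
    """A parameter value violates a declared invariant.

    Carries the offending field name so callers (and the CLI) can report
    exactly which constraint failed.
    """

    def __init__(self, field: str, constraint: str):
        self.field = field
        self.constraint = constraint
        super().__init__(f"{field}: {constraint}")


class FormatError(RenalCEAError, ValueError):
    """A parameter file could not be parsed into the documented schema."""


class DomainError(RenalCEAError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(RenalCEAError, RuntimeError):
    """A model configuration that cannot terminate or is self-contradictory."""


class ContractError(RenalCEAError, RuntimeError):
    """An internal calling contract was violated (e.g. transition from DEAD)."""
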