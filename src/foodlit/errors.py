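"""Exception hierarchy shared across the package."""


class FoodlitError(Exception):
    """Base class for all package-specific errors."""


class InstrumentSchemaError(FoodlitError):
    """An instrument config does not parse against the documented schema."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InstrumentValidationError(FoodlitError):
    """A loaded instrument violates one or more structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"instrument failed validation: {lines}")


class ResponseError(FoodlitError):
    """A respondent answer set is incomplete or references unknown options."""


class DataError(FoodlitError):
    """Tabular input is malformed or missing required columns/rows."""


class ComputationError(FoodlitError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
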