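"""Exception hierarchy shared across the package."""


class DeescbiasError(Exception):
    """Base class for all package errors."""


class SchemaError(DeescbiasError):
    """A required column is missing or mistyped in an input table."""


class DataError(DeescbiasError):
    """A row-level problem: an unparseable value or an impossible record."""


class UnknownDrugError(DeescbiasError):
    """A regimen contains a drug that the rank table does not know.

    Unknown names are hard errors by design: silently defaulting a drug's
    spectrum rank would corrupt the de-escalation classification.
    """

    def __init__(self, drug: str):
        self.drug = drug
        super().__init__(
            f"unknown antibiotic {drug!r}: add it (or a synonym) to the rank table"
        )


class InfeasibleScenarioError(DeescbiasError):
    """A confounder scenario's prevalence/odds-ratio targets cannot coexist."""


class CalibrationError(DeescbiasError):
    """The synthetic-cohort generator cannot reach a requested marginal."""


class SeparationError(DeescbiasError):
    """Logistic fit hit (quasi-)complete separation; retry with ridge=True."""


class ConvergenceError(DeescbiasError):
    """An iterative fit failed to converge."""
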