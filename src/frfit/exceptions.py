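"""Exception hierarchy for feeding-trial analysis errors."""


class FRFitError(Exception):
    """Base class for all frfit errors."""


class SchemaError(FRFitError):
    """Input table is missing required columns or is unreadable."""


class ValidationError(FRFitError):
    """Input rows violate the trial schema (e.g. eaten > offered)."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(f"line {line}: {reason}" for line, reason in self.violations)
        super().__init__(f"invalid trial rows: {msg}")


class InsufficientDataError(FRFitError):
    """Fewer than two distinct prey densities: model unidentifiable."""


class DegenerateDataError(FRFitError):
    """All-zero or all-total consumption: no density signal to classify."""


class CompleteSeparationError(FRFitError):
    """Logistic model is separated; coefficients would be unstable."""


class UnidentifiableDataError(FRFitError):
    """Likelihood has no interior maximum (e.g. zero total consumption)."""


class ConvergenceError(FRFitError):
    """Optimiser failed from every start; carries the best point found."""

    def __init__(self, message, best_point=None):
        super().__init__(message)
        self.best_point = best_point


class BootstrapInstabilityError(FRFitError):
    """More than the tolerated share of bootstrap replicates failed."""
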