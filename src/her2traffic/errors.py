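"""Exception types shared across the package."""


class Her2TrafficError(Exception):
    """Base class for package-specific errors."""


class ValidationError(Her2TrafficError, ValueError):
    """Invalid parameter, schedule or table input."""


class DegenerateSteadyStateError(ValidationError):
    """Steady-state completion requested for an inconsistent configuration
    (nonzero production feeding an empty internal pool)."""


class NumericStateError(Her2TrafficError):
    """State vector became non-finite or negative beyond tolerance."""


class IntegrationError(Her2TrafficError):
    """ODE solver failure; carries the failing time interval."""

    def __init__(self, message: str, interval=None):
        super().__init__(message)
        self.interval = interval


class DegenerateRatioError(Her2TrafficError, ZeroDivisionError):
    """Membrane-receptor ratio with a (near-)zero denominator."""


class MissingBackgroundError(ValidationError):
    """A picture has cell records but no background measurement."""


class UnidentifiableDesignError(ValidationError):
    """The additive signal/background design matrix is rank deficient."""


class FitFailureError(Her2TrafficError):
    """No multistart optimization converged to an acceptable solution."""

    def __init__(self, message: str, ensemble=None):
        super().__init__(message)
        self.ensemble = ensemble


class RefitNeededError(Her2TrafficError):
    """A nested (reduced) model fit beat the full model beyond numerical
    tolerance, signalling optimizer failure in the full fit."""
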