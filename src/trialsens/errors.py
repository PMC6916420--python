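"""Exception types shared across the package."""


class TrialSensError(ValueError):
    """Base class for all trialsens errors."""


class ValidationError(TrialSensError):
    """A trial table or model violates a structural invariant."""


class UndefinedStatisticError(TrialSensError):
    """A test statistic is undefined (zero denominator, empty arm, ...)."""


class BoundarySolutionError(TrialSensError):
    """The constrained null estimate lies on the boundary of (0, 1)."""


class DegenerateVarianceError(TrialSensError):
    """The score variance is non-positive for the given table."""


class InfeasibleParameterError(TrialSensError):
    """Requested parameters do not define a valid missingness mechanism."""
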