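"""Exception hierarchy shared across the package."""


class LysisDesignError(Exception):
    """Base class for all package-specific errors."""


class DesignDomainError(LysisDesignError, ValueError):
    """A numeric argument is outside the model's physical domain."""


class UsageError(LysisDesignError, ValueError):
    """An operation was applied to the wrong kind of object."""


class SchemaError(LysisDesignError, ValueError):
    """A library or curve table violates the expected schema."""


class FitError(LysisDesignError, RuntimeError):
    """A characterization fit is non-identifiable or failed to converge."""


class CalibrationError(LysisDesignError, RuntimeError):
    """Demo-library calibration could not reach the tracking tolerance."""


class IntegrationError(LysisDesignError, RuntimeError):
    """The ODE/SDE integrator produced a non-finite state."""


class TargetRangeError(LysisDesignError, ValueError):
    """A requested target density is unreachable on the feasible inducer range.

    Carries the attainable density interval so callers can report it.
    """

    def __init__(self, message: str, attainable: tuple[float, float] | None = None):
        super().__init__(message)
        self.attainable = attainable
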