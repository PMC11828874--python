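"""Exception hierarchy for the dicentric biodosimetry toolkit."""


class DicentricError(Exception):
    """Base class for all package-specific errors."""


class InputError(DicentricError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(DicentricError, ValueError):
    """A simulation or run configuration is internally inconsistent."""


class DesignError(DicentricError, ValueError):
    """A calibration design cannot identify the requested model."""


class FitConvergenceError(DicentricError, RuntimeError):
    """The iterative fit did not converge; carries the last iterate."""

    def __init__(self, message, last_curve=None):
        super().__init__(message)
        self.last_curve = last_curve


class CapabilityError(DicentricError, ValueError):
    """A requested method needs information the inputs do not carry."""


class ValidationError(DicentricError, ValueError):
    """A file or table violates its format invariants."""
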