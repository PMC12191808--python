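"""Exception hierarchy shared across the pipeline."""


class CamolaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CamolaError, ValueError):
    """An input violates a structural invariant (bad formula, negative area, ...)."""


class DegenerateInputError(CamolaError, ValueError):
    """An input is structurally valid but carries no usable signal (all-zero envelope, SStot = 0 design, ...)."""


class FitFailureError(CamolaError, RuntimeError):
    """A nonlinear fit did not converge after the bounded restart schedule.

    Carries the residuals of the last attempt in :attr:`last_residuals` when available.
    """

    def __init__(self, message: str, last_residuals=None):
        super().__init__(message)
        self.last_residuals = last_residuals
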