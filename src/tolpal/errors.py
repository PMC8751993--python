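"""Exception types shared across the package."""


class TolPalError(Exception):
    """Base class for package errors."""


class ValidationError(TolPalError, ValueError):
    """Invalid user input (bad parameter, mismatched grids, unknown mode)."""


class ConvergenceError(TolPalError, RuntimeError):
    """A steady-state solve failed to reach the requested tolerance."""


class IntegrationError(TolPalError, RuntimeError):
    """A time integration failed; carries the last successful time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class FitError(TolPalError, RuntimeError):
    """A fit produced a non-finite or degenerate cost."""
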