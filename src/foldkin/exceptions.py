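"""Error types raised by the fitting and I/O layers."""


class FoldkinError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FoldkinError, ValueError):
    """A dataset or argument violates a precondition."""


class FitFailureError(FoldkinError, RuntimeError):
    """Nonlinear fit did not converge after multi-start.

    Carries the best residual norm seen across starts (``best_residual``,
    may be None if no start produced a finite evaluation).
    """

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class UnderdeterminedFitError(FitFailureError):
    """Data do not constrain the model (e.g. single-limb chevron)."""

    def __init__(self, message: str):
        super().__init__(message, best_residual=None)


class DegenerateNormalizationError(FoldkinError, ZeroDivisionError):
    """Native and denatured baselines coincide at some point."""


class NumericalError(FoldkinError, ArithmeticError):
    """A derived quantity is numerically invalid (e.g. negative variance)."""
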