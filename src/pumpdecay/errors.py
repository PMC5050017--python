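"""Exception types shared across the package."""


class PumpDecayError(Exception):
    """Base class for all package errors."""


class ValidationError(PumpDecayError, ValueError):
    """A parameter set, protocol or configuration violates its invariants."""


class DomainError(PumpDecayError, ValueError):
    """An input is outside the physical domain of an operation."""


class SolverError(PumpDecayError, RuntimeError):
    """A root finder or ODE integrator failed to converge.

    ``diagnostics`` carries solver state (iterations, residual, bracket)
    for post-mortem inspection.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitError(PumpDecayError, RuntimeError):
    """A least-squares fit failed or the data are degenerate."""


class FormatError(PumpDecayError, ValueError):
    """A trace file does not conform to the declared CSV dialect."""


class SaturationError(DomainError):
    """A fluorescence ratio lies at or beyond the dye's saturation bound."""

    def __init__(self, ratio: float, bound: float):
        super().__init__(
            f"fluorescence ratio {ratio:g} is at or beyond the single-site "
            f"saturation bound {bound:.4f}; free Ca is not recoverable"
        )
        self.ratio = ratio
        self.bound = bound
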