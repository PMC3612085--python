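"""Exception types shared across the package."""


class PerfusimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PerfusimError):
    """A scenario / geometry / parameter block is inconsistent."""


class OutOfDomainError(PerfusimError):
    """A position lies outside the simulation box."""


class WellPosednessError(ConfigurationError):
    """Boundary conditions do not admit a solution (e.g. inlet with no outlet)."""


class SolverError(PerfusimError):
    """A linear or nonlinear solve failed or did not converge.

    Carries the residual history when available.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []


class ConsistencyError(PerfusimError):
    """An internal invariant was violated (e.g. negative concentration)."""
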