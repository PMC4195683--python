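"""Exception hierarchy for the sixmp package."""


class SixmpError(Exception):
    """Base class for all package-specific errors."""


class InvalidActivityError(SixmpError, ValueError):
    """TPMT activity outside [0, e_max] or non-positive e_max."""


class DomainError(SixmpError, ValueError):
    """State or argument outside the physical domain (e.g. negative cell count)."""


class SingularStateError(SixmpError, ValueError):
    """A state that makes the equations singular (e.g. zero circulating RBCs)."""


class InfeasibleBaselineError(SixmpError, ValueError):
    """Parameters admit no positive drug-free equilibrium."""


class ConfigError(SixmpError, ValueError):
    """Malformed or invalid run configuration."""


class InsufficientDataError(SixmpError, ValueError):
    """Too few observations for the requested operation."""


class NoFeasibleCandidateError(SixmpError, RuntimeError):
    """Optimizer budget exhausted without any feasible evaluation."""


class NumericalError(SixmpError, RuntimeError):
    """Integrator or solver failure; message names the failing segment."""


class AlignmentError(SixmpError, ValueError):
    """Trajectories not on a common time grid."""
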