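"""Exception hierarchy for admissibility and solver failures."""


class BrainPoroError(Exception):
    """Base class for all package-specific errors."""


class InvalidDeformationError(BrainPoroError):
    """Deformation gradient is non-finite, non-invertible or has non-positive stretches."""


class InvalidStateError(BrainPoroError):
    """An internal-variable or quadrature-point state violates its invariants."""


class CompactionError(BrainPoroError):
    """The Jacobian reached the compaction point J_S <= n0S: all pores closed,
    the solid incompressibility constraint forbids further volume reduction."""


class StepFailureError(BrainPoroError):
    """A local or global Newton iteration failed to converge; the caller should
    cut the time step and retry."""


class SolverError(BrainPoroError):
    """Hard solver failure (non-convergence at the minimum admissible step)."""


class FormatError(BrainPoroError):
    """Malformed experiment-record file."""


class ContractError(BrainPoroError):
    """A postprocessing routine was handed a trajectory lacking required data."""
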