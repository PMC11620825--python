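"""High-level drivers for the cylindrical-specimen simulation studies.

These wrap mesh construction, boundary conditions and the protocol runner
into one-call experiments: cyclic compression--tension at constant strain
rate and fast-ramp compression (or tension) relaxation with a drained hull.
They are the workhorses behind the parameter studies, the synthetic-data
generator and the inverse identification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .fem import BCSpec, FESolver, SolverControls, Trajectory
from .mesh import MeshSpec, build_quarter_cylinder_mesh
from .params import MaterialParameters, cortex_study_parameters
from .protocols import (ExperimentRecord, LoadProtocol, RelaxationMetrics,
                        make_cyclic_protocol, make_relaxation_protocol,
                        relaxation_metrics)

#: mesh resolutions (n_circum, n_radial, n_axial); "paper" reproduces the
#: 384-element discretisation, "coarse" is the default working resolution,
#: "tiny" a 3-element mesh for fitting loops
RESOLUTIONS = {"paper": (4, 4, 8), "coarse": (2, 2, 2), "tiny": (1, 1, 1)}


def specimen_mesh(radius: float = 4.0, height: float = 3.4,
                  resolution: str | tuple = "coarse"):
    if isinstance(resolution, str):
        resolution = RESOLUTIONS[resolution]
    nc, nr, nz = resolution
    return build_quarter_cylinder_mesh(
        MeshSpec(radius=radius, height=height, n_circum=nc, n_radial=nr,
                 n_axial=nz))


def trajectory_record(traj: Trajectory) -> ExperimentRecord:
    """Summary time series as a simulated experiment record."""
    df = traj.summary
    return ExperimentRecord(df["t_s"].to_numpy(),
                            df["applied_disp_mm"].to_numpy(),
                            df["nominal_stress_Pa"].to_numpy(),
                            provenance="simulated")


def simulate_protocol(params: MaterialParameters, protocol: LoadProtocol,
                      radius: float = 4.0, height: float = 3.4,
                      resolution: str | tuple = "coarse",
                      controls: SolverControls | None = None,
                      snapshot_times: Sequence[float] | None = None,
                      ) -> Trajectory:
    """Run one displacement protocol on the glued, hull-drained specimen."""
    mesh = specimen_mesh(radius, height, resolution)
    solver = FESolver(mesh, params, bc=BCSpec.specimen(), controls=controls)
    return solver.run_protocol(protocol, snapshot_times=snapshot_times)


def make_forward(radius: float = 4.0, height: float = 3.4,
                 resolution: str | tuple = "tiny",
                 controls: SolverControls | None = None):
    """A ``forward(params, protocol) -> ExperimentRecord`` closure sharing one
    mesh across calls (the shape fitting loops expect)."""
    mesh = specimen_mesh(radius, height, resolution)

    def forward(params: MaterialParameters,
                protocol: LoadProtocol) -> ExperimentRecord:
        solver = FESolver(mesh, params, bc=BCSpec.specimen(),
                          controls=controls)
        return trajectory_record(solver.run_protocol(protocol))

    return forward


@dataclass
class RelaxationStudy:
    """One fast-ramp compression-relaxation run and its read-outs."""

    trajectory: Trajectory
    record: ExperimentRecord
    metrics: RelaxationMetrics


def relaxation_study(lambda_star: float = 1e4, K0: float = 1e-7,
                     radius: float = 4.0, height: float = 3.4,
                     strain: float = -0.15, ramp_rate: float = 2.5,
                     hold: float = 600.0,
                     params: MaterialParameters | None = None,
                     resolution: str | tuple = "coarse",
                     controls: SolverControls | None = None,
                     ) -> RelaxationStudy:
    """Ramp at 2.5/s to 15 % compression, hold 600 s, drained hull;
    poroelastic visual-cortex Ogden parameters unless overridden."""
    if params is None:
        params = cortex_study_parameters(lambda_star=lambda_star, K0=K0)
    proto = make_relaxation_protocol(strain, ramp_rate, hold, height)
    traj = simulate_protocol(params, proto, radius, height, resolution,
                             controls)
    rec = trajectory_record(traj)
    return RelaxationStudy(trajectory=traj, record=rec,
                           metrics=relaxation_metrics(rec))


def cyclic_study(lambda_star: float = 1e4, K0: float = 1e-7,
                 radius: float = 4.0, height: float = 3.4,
                 amplitude: float = 0.15, rate: float = 0.01,
                 n_cycles: int = 1,
                 params: MaterialParameters | None = None,
                 resolution: str | tuple = "coarse",
                 controls: SolverControls | None = None) -> Trajectory:
    """Triangle-wave compression--tension cycles at 0.01/s strain rate."""
    if params is None:
        params = cortex_study_parameters(lambda_star=lambda_star, K0=K0)
    proto = make_cyclic_protocol(amplitude, n_cycles, rate, height)
    if controls is None:
        # resolve the dissipation-rate transients between direction changes
        controls = SolverControls(dt_max=1.0)
    return simulate_protocol(params, proto, radius, height, resolution,
                             controls)
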