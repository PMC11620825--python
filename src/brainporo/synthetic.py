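"""Synthetic experiment records with the structure of the rheometer data.

The generator runs the forward model for each requested protocol, resamples
the nominal-stress history to an acquisition grid (dense during ramps and
cycles, sparse during holds) and adds i.i.d. Gaussian measurement noise to
the stress channel only.  Records are bit-reproducible for a fixed seed.
A generated cyclic record from the fitted poro-viscoelastic parameter range
shows the two signatures the model is meant to capture: hysteresis and
compression--tension asymmetry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .params import MaterialParameters
from .protocols import (ExperimentRecord, LoadProtocol, read_experiment_csv,
                        write_experiment_csv)

__all__ = ["SyntheticSpec", "generate_dataset", "load_experiment_csv",
           "write_dataset"]


@dataclass
class SyntheticSpec:
    """Generating parameters, geometry, protocols and noise model."""

    params: MaterialParameters
    radius: float = 4.0            # mm
    height: float = 3.4            # mm
    protocols: Sequence[LoadProtocol] = ()
    noise_sigma: float = 5.0       # Pa, additive homoscedastic Gaussian
    ramp_hz: float = 10.0          # sampling rate while displacement changes
    hold_hz: float = 1.0           # sampling rate during holds
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.protocols:
            raise ValueError("need at least one protocol")


def _sampling_grid(protocol: LoadProtocol, ramp_hz: float,
                   hold_hz: float) -> np.ndarray:
    """Per-segment sampling times: dense on ramps, sparse on holds."""
    ts = [0.0]
    for (t0, d0), (t1, d1) in protocol.segments():
        hz = hold_hz if d0 == d1 else ramp_hz
        n = max(int(round((t1 - t0) * hz)), 2)
        ts.extend(np.linspace(t0, t1, n + 1)[1:])
    return np.unique(np.asarray(ts))


def generate_dataset(spec: SyntheticSpec,
                     forward: Callable) -> list[ExperimentRecord]:
    """Run ``forward(params, protocol) -> ExperimentRecord`` per protocol,
    resample, add noise; provenance is tagged ``synthetic``."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for proto in spec.protocols:
        sim = forward(spec.params, proto)
        t = _sampling_grid(proto, spec.ramp_hz, spec.hold_hz)
        stress = np.interp(t, sim.t, sim.nominal_stress)
        disp = proto.displacement(t)
        noise = rng.normal(0.0, spec.noise_sigma, size=len(t)) \
            if spec.noise_sigma > 0 else 0.0
        out.append(ExperimentRecord(t, disp, stress + noise,
                                    provenance="synthetic"))
    return out


def load_experiment_csv(path) -> ExperimentRecord:
    """Parse a t_s/disp_mm/stress_Pa CSV into an experiment record,
    validating monotone time and numeric cells."""
    return read_experiment_csv(path)


def write_dataset(records: Sequence[ExperimentRecord], spec: SyntheticSpec,
                  outdir) -> list[Path]:
    """Write records plus a JSON manifest recording the generating spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(records):
        p = outdir / f"record_{i:02d}.csv"
        write_experiment_csv(rec, p)
        paths.append(p)
    manifest = dict(
        params=spec.params.to_config(),
        radius_mm=spec.radius, height_mm=spec.height,
        noise_sigma_Pa=spec.noise_sigma, ramp_hz=spec.ramp_hz,
        hold_hz=spec.hold_hz, seed=spec.seed,
        protocols=[dict(kind=p.kind, breakpoints=list(p.breakpoints))
                   for p in spec.protocols],
        files=[p.name for p in paths],
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths
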