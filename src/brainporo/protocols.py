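"""Loading protocols and derived observables of the specimen experiments.

Protocols are piecewise-linear applied axial displacements of the top
surface: triangle-wave compression--tension cycles and ramp-and-hold
relaxation tests.  Rates may be given either as a strain rate (1/s, applied
to the specimen height) or as a crosshead speed in um/s, matching how the
two experiment families are specified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, FormatError

__all__ = [
    "LoadProtocol",
    "ExperimentRecord",
    "make_cyclic_protocol",
    "make_relaxation_protocol",
    "relaxation_metrics",
    "RelaxationMetrics",
    "field_postprocess",
    "FieldObservables",
    "read_experiment_csv",
    "write_experiment_csv",
]


@dataclass(frozen=True)
class LoadProtocol:
    """Piecewise-linear applied axial displacement versus time.

    ``breakpoints`` is a sequence of ``(t_s, displacement_mm)`` pairs with
    strictly increasing times starting at ``(0, 0)``.  Negative displacement
    compresses the specimen.
    """

    breakpoints: tuple
    kind: str = "custom"            # cyclic | relax_compression | relax_tension
    rate: float | None = None
    rate_unit: str | None = None    # "per_s" (strain rate) or "um_per_s"

    def __post_init__(self):
        bp = tuple((float(t), float(d)) for t, d in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        t = np.array([b[0] for b in bp])
        if len(bp) < 2 or bp[0][0] != 0.0:
            raise ValueError("protocol must start at t = 0 with >= 2 breakpoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([b[0] for b in self.breakpoints])

    @property
    def displacements_mm(self) -> np.ndarray:
        return np.array([b[1] for b in self.breakpoints])

    @property
    def duration(self) -> float:
        return self.breakpoints[-1][0]

    def displacement(self, t) -> np.ndarray:
        """Applied displacement (mm) at time(s) ``t`` by linear interpolation."""
        return np.interp(t, self.times, self.displacements_mm)

    def segments(self):
        """Iterate over ((t0, d0), (t1, d1)) linear segments."""
        for b0, b1 in zip(self.breakpoints[:-1], self.breakpoints[1:]):
            yield b0, b1


def _speed_mm_per_s(rate: float, height_mm: float, rate_unit: str) -> float:
    if rate_unit == "per_s":
        return rate * height_mm
    if rate_unit == "um_per_s":
        return rate * 1e-3
    raise ValueError(f"unknown rate unit {rate_unit!r}")


def make_cyclic_protocol(strain_amplitude: float, n_cycles: int, rate: float,
                         height: float, rate_unit: str = "per_s") -> LoadProtocol:
    """Triangle-wave compression--tension cycles at constant crosshead speed.

    Each cycle runs 0 -> -amplitude*h -> +amplitude*h -> 0.  With amplitude
    0.15 and strain rate 0.01/s a cycle lasts 60 s, with direction changes at
    15 s and 45 s of the first cycle.
    """
    if not (0.0 < strain_amplitude < 1.0):
        raise ValueError("strain amplitude must lie in (0, 1)")
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    amp_mm = strain_amplitude * height
    v = _speed_mm_per_s(rate, height, rate_unit)
    bp = [(0.0, 0.0)]
    t = 0.0
    for _ in range(n_cycles):
        for d in (-amp_mm, amp_mm, 0.0):
            t += abs(d - bp[-1][1]) / v
            bp.append((t, d))
    return LoadProtocol(tuple(bp), kind="cyclic", rate=rate, rate_unit=rate_unit)


def make_relaxation_protocol(strain: float, ramp_rate: float, hold: float,
                             height: float, rate_unit: str = "per_s") -> LoadProtocol:
    """Single linear ramp to ``strain`` (signed; negative = compression)
    followed by a constant displacement hold."""
    if hold <= 0:
        raise ValueError("hold duration must be positive")
    if strain == 0.0:
        raise ValueError("strain must be nonzero")
    d_mm = strain * height
    v = _speed_mm_per_s(ramp_rate, height, rate_unit)
    t_ramp = abs(d_mm) / v
    kind = "relax_compression" if strain < 0 else "relax_tension"
    return LoadProtocol(((0.0, 0.0), (t_ramp, d_mm), (t_ramp + hold, d_mm)),
                        kind=kind, rate=ramp_rate, rate_unit=rate_unit)


@dataclass
class ExperimentRecord:
    """A (time, applied displacement, nominal stress) series.

    ``provenance`` is one of measured | synthetic | simulated.  Times in s,
    displacement in mm, nominal stress in Pa (compression negative).
    """

    t: np.ndarray
    displacement: np.ndarray
    nominal_stress: np.ndarray
    provenance: str = "measured"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.nominal_stress = np.asarray(self.nominal_stress, dtype=float)
        n = len(self.t)
        if len(self.displacement) != n or len(self.nominal_stress) != n:
            raise ValueError("record channels must have equal length")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("record times must be non-decreasing")

    def __len__(self):
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "disp_mm": self.displacement,
                             "stress_Pa": self.nominal_stress})

    def subset(self, idx) -> "ExperimentRecord":
        return ExperimentRecord(self.t[idx], self.displacement[idx],
                                self.nominal_stress[idx], self.provenance)


REQUIRED_COLUMNS = ("t_s", "disp_mm", "stress_Pa")


def write_experiment_csv(record: ExperimentRecord, path) -> None:
    record.to_frame().to_csv(path, index=False)


def read_experiment_csv(path, provenance: str = "measured") -> ExperimentRecord:
    """Read the t_s/disp_mm/stress_Pa CSV dialect; extra columns are ignored."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for c in REQUIRED_COLUMNS:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(f"{path}: non-numeric value in column {c!r}, row {row}")
        if df[c].isna().any():
            row = int(np.flatnonzero(df[c].isna())[0])
            raise FormatError(f"{path}: missing value in column {c!r}, row {row}")
    t = df["t_s"].to_numpy(float)
    dec = np.flatnonzero(np.diff(t) < 0)
    if dec.size:
        raise FormatError(f"{path}: time decreases at row {int(dec[0]) + 1}")
    return ExperimentRecord(t, df["disp_mm"].to_numpy(float),
                            df["stress_Pa"].to_numpy(float), provenance)


# ---------------------------------------------------------------------------
# derived observables
# ---------------------------------------------------------------------------

@dataclass
class RelaxationMetrics:
    """Peak/equilibrium read-outs of a ramp-and-hold record.

    ``relaxation_fraction`` is the percentage drop from the peak stress at
    the end of the ramp to the equilibrium stress (mean over the final 1 % of
    the hold).  ``normalized`` is stress/peak; ``normalized_shifted`` is
    (stress - equilibrium)/(peak - equilibrium) over the hold, starting at 1
    and decaying towards 0 (undefined when the record does not relax)."""

    peak_stress: float
    equilibrium_stress: float
    relaxation_fraction: float
    t_hold: np.ndarray
    normalized: np.ndarray
    normalized_shifted: np.ndarray | None
    degenerate: bool = False

    def time_to_fraction(self, fraction: float = 0.9) -> float:
        """First time (s, from ramp end) at which the given fraction of the
        total peak-to-equilibrium relaxation has occurred."""
        if self.degenerate or self.normalized_shifted is None:
            raise ContractError("record does not relax; time scale undefined")
        decayed = 1.0 - self.normalized_shifted
        idx = np.flatnonzero(decayed >= fraction)
        if idx.size == 0:
            return float("inf")
        return float(self.t_hold[idx[0]] - self.t_hold[0])


def relaxation_metrics(record: ExperimentRecord,
                       equilibrium_window: float = 0.01) -> RelaxationMetrics:
    """Compute peak stress, equilibrium stress and relaxation fraction.

    The peak is the stress at the last ramp sample (first time the applied
    displacement reaches its held value); the equilibrium level is the mean
    stress over the final ``equilibrium_window`` fraction of the hold.
    """
    d = record.displacement
    d_hold = d[-1]
    tol = 1e-9 * (np.abs(d).max() + 1e-30) + 1e-12
    ramp_end = int(np.flatnonzero(np.abs(d - d_hold) <= tol)[0])
    peak = float(record.nominal_stress[ramp_end])
    if peak == 0.0:
        raise ContractError("zero peak stress: normalization undefined")
    t_hold = record.t[ramp_end:]
    s_hold = record.nominal_stress[ramp_end:]
    hold_dur = t_hold[-1] - t_hold[0]
    win = record.t[-1] - equilibrium_window * hold_dur
    eq = float(s_hold[t_hold >= win].mean())
    frac = 100.0 * (abs(peak) - abs(eq)) / abs(peak)
    normalized = s_hold / peak
    degenerate = abs(peak - eq) < 1e-12 * abs(peak)
    shifted = None if degenerate else (s_hold - eq) / (peak - eq)
    return RelaxationMetrics(peak_stress=peak, equilibrium_stress=eq,
                             relaxation_fraction=frac, t_hold=t_hold,
                             normalized=normalized, normalized_shifted=shifted,
                             degenerate=degenerate)


@dataclass
class FieldObservables:
    """Volume-integrated and surface observables extracted from a trajectory."""

    t: np.ndarray
    lateral_disp_mm: np.ndarray
    Dp_total: np.ndarray
    Dv_total: np.ndarray
    pressure_snapshots: list
    JS_snapshots: list
    snapshot_times: list


def field_postprocess(trajectory, snapshot_times: Sequence[float] | None = None
                      ) -> FieldObservables:
    """Collect lateral displacement, dissipation totals and field snapshots.

    The lateral displacement is the maximum radial displacement over the hull
    ring at half specimen height.  Dissipation totals are the volume
    integrals of the viscous and porous dissipation power densities (W).
    """
    df = trajectory.summary
    needed = {"t_s", "lateral_disp_mm", "Dp_total_W", "Dv_total_W"}
    if not needed.issubset(df.columns):
        raise ContractError("trajectory lacks required summary columns")
    snaps_p, snaps_J, times = [], [], []
    if snapshot_times is not None:
        available = {round(s.t, 9): s for s in trajectory.snapshots}
        for ts in snapshot_times:
            key = round(float(ts), 9)
            if key not in available:
                raise ContractError(f"no snapshot recorded at t = {ts} s")
            s = available[key]
            snaps_p.append(s.p)
            snaps_J.append(s.JS)
            times.append(float(ts))
    return FieldObservables(
        t=df["t_s"].to_numpy(), lateral_disp_mm=df["lateral_disp_mm"].to_numpy(),
        Dp_total=df["Dp_total_W"].to_numpy(), Dv_total=df["Dv_total_W"].to_numpy(),
        pressure_snapshots=snaps_p, JS_snapshots=snaps_J, snapshot_times=times)
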