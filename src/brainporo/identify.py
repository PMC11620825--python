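"""Inverse material-parameter identification against stress--time records.

The objective is the root-mean-square error (Pa) between simulated and
recorded nominal stress, pooled over all fitted protocols; it is minimised
by bound-constrained trust-region-reflective nonlinear least squares with a
finite-difference Jacobian.  The permeability is fitted on a log10 scale
because candidate values span many orders of magnitude, and multi-start
(Latin hypercube) initialisation guards against the known non-uniqueness of
the six-parameter poro-viscoelastic set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .exceptions import BrainPoroError, SolverError, StepFailureError
from .params import MaterialParameters
from .protocols import ExperimentRecord, LoadProtocol

log = logging.getLogger(__name__)

__all__ = [
    "FitSpec", "FitResult", "preprocess_signal", "moving_average",
    "rdp_simplify", "objective_rmse", "fit_parameters",
    "POROELASTIC_FREE", "POROVISCOELASTIC_FREE",
]

#: objective value substituted when the forward solver fails at a trial point
FAILURE_PENALTY = 1e6

POROELASTIC_FREE = ("mu_inf", "alpha_inf", "log10_K0")
POROVISCOELASTIC_FREE = ("mu_inf", "alpha_inf", "mu_1", "alpha_1", "eta",
                         "log10_K0")

#: default fitting bounds (natural/transformed units); moduli and
#: nonlinearities use the negative branch of mu*alpha > 0 as in brain tissue
DEFAULT_BOUNDS = {
    "mu_inf": (-1e4, -1.0),
    "alpha_inf": (-30.0, -0.5),
    "mu_1": (-1e4, -1.0),
    "alpha_1": (-30.0, -0.5),
    "eta": (10.0, 1e5),
    "lambda_star": (10.0, 1e5),
    "log10_K0": (-12.0, -3.0),
}


# ---------------------------------------------------------------------------
# signal preprocessing
# ---------------------------------------------------------------------------

def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(y):
        raise ValueError("window larger than the series")
    return (pd.Series(y).rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def _rdp_keep_mask(x: np.ndarray, y: np.ndarray, epsilon: float) -> np.ndarray:
    """Ramer-Douglas-Peucker: boolean keep-mask via iterative farthest-point
    splitting; endpoints are always kept."""
    n = len(x)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i0, i1 = stack.pop()
        if i1 <= i0 + 1:
            continue
        dx, dy = x[i1] - x[i0], y[i1] - y[i0]
        seg = np.hypot(dx, dy)
        xs, ys = x[i0 + 1:i1], y[i0 + 1:i1]
        if seg == 0.0:
            d = np.hypot(xs - x[i0], ys - y[i0])
        else:
            d = np.abs(dy * xs - dx * ys + x[i1] * y[i0] - y[i1] * x[i0]) / seg
        j = int(np.argmax(d))
        if d[j] > epsilon:
            k = i0 + 1 + j
            keep[k] = True
            stack.append((i0, k))
            stack.append((k, i1))
    return keep


def rdp_simplify(x: np.ndarray, y: np.ndarray, epsilon: float) -> np.ndarray:
    """Indices of the polyline points kept at perpendicular tolerance epsilon.

    ``epsilon = 0`` keeps every point; collinear interior points are dropped
    for any positive tolerance.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0.0:
        return np.arange(len(x))
    return np.flatnonzero(_rdp_keep_mask(np.asarray(x, float),
                                         np.asarray(y, float), epsilon))


def preprocess_signal(record: ExperimentRecord, window: int = 5,
                      epsilon: float = 0.5) -> ExperimentRecord:
    """Moving-average smoothing of the stress channel followed by
    Ramer-Douglas-Peucker thinning on the (t, stress) polyline.

    ``window`` in samples (odd), ``epsilon`` in Pa.  Returns a record with
    fewer (or equal) points; times stay monotone, displacement is carried
    along at the kept samples.
    """
    smooth = moving_average(record.nominal_stress, window)
    idx = rdp_simplify(record.t, smooth, epsilon)
    return ExperimentRecord(record.t[idx], record.displacement[idx],
                            smooth[idx], record.provenance)


# ---------------------------------------------------------------------------
# objective and fitting
# ---------------------------------------------------------------------------

@dataclass
class FitSpec:
    """What to fit and how.

    ``free`` lists parameter names (``log10_K0`` fits the permeability on a
    log scale); ``base`` supplies all fixed values, e.g. a pinned
    ``lambda_star``.  ``protocols`` pairs each target record with the load
    protocol that produced it.  Optional ``x0`` overrides the multi-start
    initialisation.
    """

    free: Sequence[str]
    base: MaterialParameters
    protocols: Sequence[LoadProtocol]
    bounds: dict = field(default_factory=dict)
    x0: Sequence[float] | None = None
    n_starts: int = 5
    max_nfev: int | None = None
    weights: Sequence[float] | None = None
    #: relative finite-difference step of the least-squares Jacobian; must
    #: sit well above the forward solver's noise floor (adaptive stepping
    #: makes the residual only piecewise smooth in the parameters)
    diff_step: float = 0.01

    def __post_init__(self):
        if not self.free:
            raise ValueError("need at least one free parameter")
        for name in self.free:
            if name not in DEFAULT_BOUNDS:
                raise ValueError(f"unknown fit parameter {name!r}")
        lo, hi = self.bounds_arrays()
        if not np.all(lo < hi):
            raise ValueError("bounds must satisfy lower < upper")

    def bounds_arrays(self):
        lo, hi = [], []
        for name in self.free:
            b = self.bounds.get(name, DEFAULT_BOUNDS[name])
            lo.append(b[0])
            hi.append(b[1])
        return np.asarray(lo, float), np.asarray(hi, float)

    def make_params(self, x: np.ndarray) -> MaterialParameters:
        changes = {}
        for name, v in zip(self.free, x):
            if name == "log10_K0":
                changes["K0"] = 10.0 ** v
            else:
                changes[name] = float(v)
        return self.base.replace(**changes)


@dataclass
class FitResult:
    """Best parameters, RMSE and diagnostics of a (multi-start) fit."""

    params: MaterialParameters
    rmse: float
    x: np.ndarray
    free: tuple
    n_iterations: int
    n_forward_evals: int
    final_gradient_norm: float
    status: int
    residuals: np.ndarray
    per_protocol_rmse: tuple
    starts: pd.DataFrame          # one row per start: x0, x, rmse, status
    jacobian: np.ndarray | None = None

    @property
    def K0_spread(self) -> float:
        """log10 spread of the fitted permeability across starts (surfaces
        the non-uniqueness of the identification; 0 when K0 was not free)."""
        if "log10_K0" not in self.free or len(self.starts) < 2:
            return 0.0
        col = self.starts[f"x_{list(self.free).index('log10_K0')}"]
        return float(col.max() - col.min())


def _pooled_residuals(params: MaterialParameters, fitspec: FitSpec,
                      targets: Sequence[ExperimentRecord],
                      forward: Callable) -> list[np.ndarray]:
    res = []
    weights = fitspec.weights or [1.0] * len(targets)
    for proto, rec, wgt in zip(fitspec.protocols, targets, weights):
        sim = forward(params, proto)
        s = np.interp(rec.t, sim.t, sim.nominal_stress)
        res.append(np.sqrt(wgt) * (s - rec.nominal_stress))
    return res


def objective_rmse(params: MaterialParameters, fitspec: FitSpec,
                   targets: Sequence[ExperimentRecord],
                   forward: Callable) -> float:
    """Pooled RMSE (Pa) of simulated vs. recorded nominal stress.

    ``forward(params, protocol) -> ExperimentRecord`` runs the forward model;
    simulated stress is linearly interpolated to the target sample times.  A
    forward-solver failure returns a large penalty instead of raising so an
    optimiser can continue elsewhere.
    """
    try:
        res = np.concatenate(
            _pooled_residuals(params, fitspec, targets, forward))
    except (SolverError, StepFailureError, BrainPoroError) as exc:
        log.warning("forward solve failed at %s: %s", params, exc)
        return FAILURE_PENALTY
    return float(np.sqrt(np.mean(res ** 2)))


def fit_parameters(fitspec: FitSpec, targets: Sequence[ExperimentRecord],
                   forward: Callable, seed: int = 0) -> FitResult:
    """Bound-constrained trust-region-reflective least squares, optionally
    multi-start from a seeded Latin hypercube."""
    lo, hi = fitspec.bounds_arrays()
    ndim = len(fitspec.free)
    if fitspec.x0 is not None:
        x0s = [np.asarray(fitspec.x0, float)]
    else:
        sampler = qmc.LatinHypercube(d=ndim, seed=seed)
        u = sampler.random(fitspec.n_starts)
        x0s = list(qmc.scale(u, lo, hi))

    nfev_total = 0

    def residual_fn(x):
        nonlocal nfev_total
        nfev_total += 1
        params = fitspec.make_params(x)
        try:
            return np.concatenate(
                _pooled_residuals(params, fitspec, targets, forward))
        except (SolverError, StepFailureError, BrainPoroError) as exc:
            log.warning("forward solve failed during fit: %s", exc)
            n = sum(len(t) for t in targets)
            return np.full(n, FAILURE_PENALTY)

    rows, results = [], []
    for x0 in x0s:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = least_squares(residual_fn, x0, bounds=(lo, hi),
                                    method="trf", x_scale="jac",
                                    diff_step=fitspec.diff_step,
                                    max_nfev=fitspec.max_nfev)
        except Exception as exc:  # pathological start
            log.warning("start %s failed: %s", x0, exc)
            rows.append({**{f"x0_{i}": v for i, v in enumerate(x0)},
                         "rmse": np.inf, "status": -99})
            continue
        rmse = float(np.sqrt(np.mean(sol.fun ** 2)))
        row = {**{f"x0_{i}": v for i, v in enumerate(x0)},
               **{f"x_{i}": v for i, v in enumerate(sol.x)},
               "rmse": rmse, "status": sol.status}
        rows.append(row)
        results.append((rmse, sol))
    starts = pd.DataFrame(rows)
    if not results:
        raise BrainPoroError("all optimizer starts failed; see diagnostics")
    results.sort(key=lambda t: t[0])
    rmse, sol = results[0]

    per_proto = []
    try:
        res_list = _pooled_residuals(fitspec.make_params(sol.x), fitspec,
                                     targets, forward)
        per_proto = [float(np.sqrt(np.mean(r ** 2))) for r in res_list]
    except (SolverError, StepFailureError, BrainPoroError):
        per_proto = [np.nan] * len(targets)

    grad = sol.jac.T @ sol.fun if sol.jac is not None else np.array([np.nan])
    return FitResult(
        params=fitspec.make_params(sol.x), rmse=rmse, x=sol.x,
        free=tuple(fitspec.free), n_iterations=getattr(sol, "nit", -1)
        if hasattr(sol, "nit") else -1,
        n_forward_evals=nfev_total,
        final_gradient_norm=float(np.linalg.norm(grad)),
        status=int(sol.status), residuals=sol.fun,
        per_protocol_rmse=tuple(per_proto), starts=starts, jacobian=sol.jac)
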