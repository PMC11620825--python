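"""Model/Results interface for fitting the tissue model to experiments.

``PoroViscoelasticTissueModel`` binds experiment records, their loading
protocols and the specimen geometry; ``fit()`` runs the bound-constrained
least-squares identification and returns ``TissueFitResults`` carrying the
estimates, linearised standard errors, diagnostics and a ``summary()``
table, in the spirit of the classic statistical-modelling packages.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .fem import SolverControls
from .identify import (FitResult, FitSpec, POROELASTIC_FREE,
                       POROVISCOELASTIC_FREE, fit_parameters, objective_rmse,
                       preprocess_signal)
from .params import MaterialParameters
from .protocols import ExperimentRecord, LoadProtocol, read_experiment_csv
from .studies import make_forward

__all__ = ["PoroViscoelasticTissueModel", "TissueFitResults"]

_PARAM_UNITS = {"mu_inf": "Pa", "alpha_inf": "-", "mu_1": "Pa", "alpha_1": "-",
                "eta": "Pa.s", "lambda_star": "Pa", "log10_K0": "log10(mm2)"}


class PoroViscoelasticTissueModel:
    """Biphasic poro-viscoelastic specimen model bound to experiment records.

    Parameters
    ----------
    records, protocols : parallel sequences of experiment records and the
        displacement protocols that produced them.
    radius, height : specimen geometry in mm.
    mode : "poroelastic" (fits mu_inf, alpha_inf, log10 K0) or
        "poroviscoelastic" (adds mu_1, alpha_1, eta).
    lambda_star : fixed first Lamé parameter (Pa), or the string "free" to
        let the optimiser identify it (lower bound 10 Pa).
    resolution : mesh resolution key or (n_circum, n_radial, n_axial).
    """

    def __init__(self, records: Sequence[ExperimentRecord],
                 protocols: Sequence[LoadProtocol],
                 radius: float = 4.0, height: float = 3.4,
                 mode: str = "poroviscoelastic",
                 lambda_star: float | str = 100.0,
                 base_params: MaterialParameters | None = None,
                 resolution="tiny",
                 controls: SolverControls | None = None,
                 bounds: dict | None = None,
                 preprocess: bool = False, window: int = 5,
                 epsilon: float = 0.5):
        if len(records) != len(protocols):
            raise ValueError("records and protocols must pair up")
        if mode not in ("poroelastic", "poroviscoelastic"):
            raise ValueError(f"unknown mode {mode!r}")
        if preprocess:
            records = [preprocess_signal(r, window, epsilon) for r in records]
        self.records = list(records)
        self.protocols = list(protocols)
        self.radius, self.height = radius, height
        self.mode = mode
        free = list(POROELASTIC_FREE if mode == "poroelastic"
                    else POROVISCOELASTIC_FREE)
        lam = 100.0 if lambda_star == "free" else float(lambda_star)
        if lambda_star == "free":
            free.append("lambda_star")
        if base_params is None:
            if mode == "poroelastic":
                base_params = MaterialParameters(
                    mu_inf=-100.0, alpha_inf=-5.0, lambda_star=lam)
            else:
                base_params = MaterialParameters(
                    mu_inf=-100.0, alpha_inf=-5.0, mu_1=-100.0, alpha_1=-5.0,
                    eta=1000.0, lambda_star=lam)
        else:
            base_params = base_params.replace(lambda_star=lam)
        self.base_params = base_params
        self.free = tuple(free)
        self.bounds = bounds or {}
        self.forward = make_forward(radius, height, resolution, controls)

    @classmethod
    def from_csv(cls, paths: Sequence, protocols: Sequence[LoadProtocol],
                 **kwargs) -> "PoroViscoelasticTissueModel":
        records = [read_experiment_csv(p) for p in paths]
        return cls(records, protocols, **kwargs)

    def fitspec(self, x0=None, n_starts: int = 5,
                max_nfev: int | None = None) -> FitSpec:
        return FitSpec(free=self.free, base=self.base_params,
                       protocols=self.protocols, bounds=self.bounds,
                       x0=x0, n_starts=n_starts, max_nfev=max_nfev)

    def simulate(self, params: MaterialParameters) -> list[ExperimentRecord]:
        """Forward-simulate every protocol at the given parameters."""
        return [self.forward(params, proto) for proto in self.protocols]

    def rmse(self, params: MaterialParameters) -> float:
        return objective_rmse(params, self.fitspec(), self.records,
                              self.forward)

    def fit(self, seed: int = 0, x0=None, n_starts: int = 5,
            max_nfev: int | None = None) -> "TissueFitResults":
        spec = self.fitspec(x0=x0, n_starts=n_starts, max_nfev=max_nfev)
        result = fit_parameters(spec, self.records, self.forward, seed=seed)
        return TissueFitResults(self, result)


class TissueFitResults:
    """Estimates, uncertainties and diagnostics of one identification run."""

    def __init__(self, model: PoroViscoelasticTissueModel, result: FitResult):
        self.model = model
        self._result = result
        self.params = result.params
        self.rmse = result.rmse
        self.x = result.x
        self.free = result.free

    @property
    def nobs(self) -> int:
        return sum(len(r) for r in self.model.records)

    @property
    def bse(self) -> np.ndarray:
        """Linearised standard errors from the Gauss-Newton approximation of
        the covariance, s^2 (J^T J)^{-1}; NaN where the information matrix is
        singular (a symptom of the known parameter non-uniqueness)."""
        J = self._result.jacobian
        r = self._result.residuals
        dof = max(self.nobs - len(self.x), 1)
        s2 = float(r @ r) / dof
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            return np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            return np.full(len(self.x), np.nan)

    @property
    def K0_spread(self) -> float:
        return self._result.K0_spread

    def params_frame(self) -> pd.DataFrame:
        bse = self.bse
        rows = []
        for i, name in enumerate(self.free):
            rows.append(dict(parameter=name, estimate=self.x[i],
                             std_err=bse[i],
                             unit=_PARAM_UNITS.get(name, "")))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r = self._result
        lines = [
            "Poro-viscoelastic tissue model fit",
            "=" * 54,
            f"mode: {self.model.mode}   protocols: "
            f"{len(self.model.protocols)}   observations: {self.nobs}",
            f"geometry: r = {self.model.radius} mm, "
            f"h = {self.model.height} mm",
            f"lambda* = {self.params.lambda_star:g} Pa"
            + (" (fitted)" if "lambda_star" in self.free else " (fixed)"),
            "-" * 54,
            f"{'parameter':<12}{'estimate':>14}{'std err':>12}  unit",
        ]
        bse = self.bse
        for i, name in enumerate(self.free):
            lines.append(f"{name:<12}{self.x[i]:>14.4g}{bse[i]:>12.3g}  "
                         f"{_PARAM_UNITS.get(name, '')}")
        lines += [
            "-" * 54,
            f"RMSE: {self.rmse:.2f} Pa   per-protocol: "
            + ", ".join(f"{v:.1f}" for v in r.per_protocol_rmse),
            f"K0 = {self.params.K0:.3g} mm^2",
            f"optimizer status {r.status}, {r.n_forward_evals} forward "
            f"evaluations, |grad| = {r.final_gradient_norm:.2e}",
        ]
        if len(r.starts) > 1:
            lines.append(f"multi-start spread of log10 K0: "
                         f"{self.K0_spread:.2f} decades over "
                         f"{len(r.starts)} starts")
        return "\n".join(lines)

    def fittedvalues(self) -> list[ExperimentRecord]:
        return self.model.simulate(self.params)

    def plot_fit(self, ax=None):
        """Overlay fitted model stress on the target records."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sims = self.fittedvalues()
        for i, (rec, sim) in enumerate(zip(self.model.records, sims)):
            ax.plot(rec.t, rec.nominal_stress, ".", ms=2,
                    label=f"data {i}" if i < 4 else None)
            ax.plot(sim.t, sim.nominal_stress, "-", lw=1.2,
                    label=f"fit {i}" if i < 4 else None)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("nominal stress (Pa)")
        ax.legend(frameon=False, fontsize=8)
        return ax
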