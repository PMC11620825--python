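"""Pointwise constitutive laws of the biphasic poro-viscoelastic solid.

All operations accept either a single tensor (shape ``(3, 3)``) or a batch
(shape ``(..., 3, 3)``) and broadcast over the leading axes; scalars such as
the Jacobian follow with shape ``(...)``.  Stresses are Kirchhoff stresses in
Pa, evaluated spectrally in principal stretches.

The solid extra stress splits into a full (volumetric + isochoric)
equilibrium Ogden branch, a purely isochoric non-equilibrium Ogden/Maxwell
branch with internal variable ``b_e`` (elastic left Cauchy-Green tensor), and
a volumetric extension function that diverges at the compaction point
``J_S -> n0S`` where all pores are closed.  The pore fluid adds ``-p J_S I``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    CompactionError,
    InvalidDeformationError,
    InvalidStateError,
    StepFailureError,
)
from .params import MaterialParameters

__all__ = [
    "QuadraturePointState",
    "StressDecomposition",
    "DissipationRates",
    "equilibrium_stress",
    "nonequilibrium_stress",
    "volumetric_stress",
    "total_stress",
    "update_viscous_state",
    "seepage_velocity",
    "dissipation_rates",
    "ogden_energy_density",
    "volumetric_energy_density",
]

_I3 = np.eye(3)

#: Local Newton settings of the viscous return mapping.
RETURN_MAP_TOL = 1e-10
RETURN_MAP_MAX_ITER = 30


@dataclass
class QuadraturePointState:
    """Deformation and internal state at one integration point.

    ``F`` is the solid deformation gradient, ``be_e`` the elastic left
    Cauchy-Green internal variable of the Maxwell branch, ``JS = det F`` and
    ``p`` the pore pressure (Pa).  At the reference state ``F = be_e = I``
    and ``p = 0``.
    """

    F: np.ndarray
    be_e: np.ndarray
    JS: float
    p: float

    @classmethod
    def reference(cls) -> "QuadraturePointState":
        return cls(F=_I3.copy(), be_e=_I3.copy(), JS=1.0, p=0.0)


@dataclass
class StressDecomposition:
    """Additive Kirchhoff-stress split tau = tau_eq + tau_neq + tau_vol - p J I."""

    tau_eq: np.ndarray
    tau_neq: np.ndarray
    tau_vol: np.ndarray
    tau_fluid: np.ndarray

    @property
    def tau_total(self) -> np.ndarray:
        return self.tau_eq + self.tau_neq + self.tau_vol + self.tau_fluid


@dataclass
class DissipationRates:
    """Viscous (Maxwell dashpot) and porous (Darcy drag) dissipation power
    densities, both non-negative by construction."""

    Dv: np.ndarray
    Dp: np.ndarray


def _spectral(b: np.ndarray):
    """Eigen-decomposition of a batch of symmetric 3x3 tensors."""
    w, V = np.linalg.eigh(b)
    return w, V


def _from_principal(beta: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Assemble sum_a beta_a n_a (x) n_a from principal values and directions."""
    return np.einsum("...a,...ia,...ja->...ij", beta, V, V)


def equilibrium_stress(F: np.ndarray, params: MaterialParameters) -> np.ndarray:
    """Equilibrium Ogden Kirchhoff stress evaluated on the *total* stretches.

    Spectral form ``sum_a beta_a n_a (x) n_a`` of ``b = F F^T`` with principal
    values ``beta_a = mu_inf [lambda_a^alpha_inf - 1]``.  The branch carries
    both volumetric and isochoric contributions.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise InvalidDeformationError("non-finite deformation gradient")
    b = F @ np.swapaxes(F, -1, -2)
    lam2, V = _spectral(b)
    if np.any(lam2 <= 0.0) or not np.all(np.isfinite(lam2)):
        raise InvalidDeformationError("non-positive principal stretch")
    lam = np.sqrt(lam2)
    beta = params.mu_inf * (lam ** params.alpha_inf - 1.0)
    return _from_principal(beta, V)


def _neq_beta_from_logstrain(eps: np.ndarray, params: MaterialParameters) -> np.ndarray:
    """Deviatoric Ogden principal stresses from elastic logarithmic stretches."""
    eps_iso = eps - eps.mean(axis=-1, keepdims=True)
    g = np.exp(params.alpha_1 * eps_iso)
    return params.mu_1 * (g - g.mean(axis=-1, keepdims=True))


def nonequilibrium_stress(be_e: np.ndarray, params: MaterialParameters) -> np.ndarray:
    """Non-equilibrium Kirchhoff stress from the elastic left Cauchy-Green tensor.

    Uses the isochoric elastic stretches ``(J_e)^{-1/3} lambda_a^e``; the
    principal values are deviatoric by construction (they sum to zero).
    """
    be_e = np.asarray(be_e, dtype=float)
    if not np.all(np.isfinite(be_e)) or np.any(
        np.abs(be_e - np.swapaxes(be_e, -1, -2)) > 1e-8 * (1.0 + np.abs(be_e))
    ):
        raise InvalidStateError("be_e must be symmetric")
    lam2, V = _spectral(be_e)
    if np.any(lam2 <= 0.0):
        raise InvalidStateError("be_e must be positive definite")
    if params.mu_1 == 0.0:
        return np.zeros_like(be_e)
    eps = 0.5 * np.log(lam2)
    beta = _neq_beta_from_logstrain(eps, params)
    return _from_principal(beta, V)


def volumetric_stress(JS, params: MaterialParameters):
    """Coefficient (Pa) of the identity in the volumetric solid stress.

    ``lambda* (1-n0S)^2 [ J/(1-n0S) - J/(J-n0S) ]``: zero at ``J = 1``,
    strictly increasing on the admissible domain and diverging to ``-inf`` at
    the compaction point ``J -> n0S``.
    """
    JS = np.asarray(JS, dtype=float)
    n = params.n0S
    if np.any(JS <= n):
        raise CompactionError(
            f"J_S <= n0S = {n}: compaction point reached, state inadmissible"
        )
    c = params.lambda_star * (1.0 - n) ** 2
    out = c * (JS / (1.0 - n) - JS / (JS - n))
    return out if out.ndim else float(out)


def total_stress(state: QuadraturePointState,
                 params: MaterialParameters) -> StressDecomposition:
    """Assemble the four Kirchhoff-stress contributions at one point."""
    tau_eq = equilibrium_stress(state.F, params)
    tau_neq = nonequilibrium_stress(state.be_e, params)
    JS = np.asarray(state.JS, dtype=float)
    tvol = np.asarray(volumetric_stress(JS, params))
    p = np.asarray(state.p, dtype=float)
    eye = np.broadcast_to(_I3, tau_eq.shape)
    tau_vol = tvol[..., None, None] * eye
    tau_fluid = (-p * JS)[..., None, None] * eye
    return StressDecomposition(tau_eq=tau_eq, tau_neq=tau_neq,
                               tau_vol=tau_vol, tau_fluid=tau_fluid)


def update_viscous_state(F_new: np.ndarray, be_e_old: np.ndarray,
                         F_old: np.ndarray, dt: float,
                         params: MaterialParameters):
    """Integrate the viscous evolution law over one step.

    Exponential-map backward Euler in principal logarithmic elastic strains:
    the trial state ``b_tr = f b_e_old f^T`` (relative deformation gradient
    ``f = F_new F_old^{-1}``) is corrected by a local Newton iteration on

        eps_a = eps_a^tr - (dt / 2 eta) beta_a(eps),

    which keeps the internal variable symmetric positive definite and the
    viscous flow exactly isochoric (the deviatoric ``beta`` preserves
    ``sum_a eps_a``).  Returns ``(be_e_new, tau_neq_new)``.

    Raises
    ------
    StepFailureError
        if the local Newton iteration does not converge; the caller should
        cut the time step.
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    F_new = np.asarray(F_new, dtype=float)
    F_old = np.asarray(F_old, dtype=float)
    be_e_old = np.asarray(be_e_old, dtype=float)
    f = F_new @ np.linalg.inv(F_old)
    b_tr = f @ be_e_old @ np.swapaxes(f, -1, -2)
    b_tr = 0.5 * (b_tr + np.swapaxes(b_tr, -1, -2))
    lam2, V = _spectral(b_tr)
    if np.any(lam2 <= 0.0) or not np.all(np.isfinite(lam2)):
        raise InvalidStateError("trial elastic state not positive definite")
    if params.mu_1 == 0.0:
        return b_tr, np.zeros_like(b_tr)

    eps_tr = 0.5 * np.log(lam2)
    eps = eps_tr.copy()
    a1, mu1 = params.alpha_1, params.mu_1
    fac = dt / (2.0 * params.eta)
    converged = np.zeros(eps.shape[:-1], dtype=bool) if eps.ndim > 1 else np.array(False)
    for _ in range(RETURN_MAP_MAX_ITER):
        beta = _neq_beta_from_logstrain(eps, params)
        r = eps - eps_tr + fac * beta
        res = np.abs(r).max(axis=-1)
        converged = res < RETURN_MAP_TOL
        if np.all(converged):
            break
        # analytic 3x3 Jacobian: d beta_a / d eps_b
        eps_iso = eps - eps.mean(axis=-1, keepdims=True)
        g = np.exp(a1 * eps_iso)                       # (..., 3)
        P = _I3 - 1.0 / 3.0                            # deviatoric projector
        dg = a1 * g[..., :, None] * P                  # (..., 3, 3)
        dbeta = mu1 * (dg - dg.mean(axis=-2, keepdims=True))
        J = _I3 + fac * dbeta
        eps = eps - np.linalg.solve(J, r[..., None])[..., 0]
    else:
        if not np.all(converged):
            raise StepFailureError("viscous return mapping did not converge")
    be_new = _from_principal(np.exp(2.0 * eps), V)
    tau_neq = _from_principal(_neq_beta_from_logstrain(eps, params), V)
    return be_new, tau_neq


def seepage_velocity(grad_p: np.ndarray, JS, params: MaterialParameters) -> np.ndarray:
    """Volume-weighted seepage velocity ``w`` (m/s) from the Darcy-like law.

    ``w = -(1/muFR) [(J-n0S)/(1-n0S)] K0 grad p`` with isotropic initial
    intrinsic permeability; the deformation-dependent prefactor closes the
    pores (``w -> 0``) at compaction.  ``grad_p`` is the spatial pressure
    gradient in Pa/m.
    """
    grad_p = np.asarray(grad_p, dtype=float)
    JS = np.asarray(JS, dtype=float)
    n = params.n0S
    if np.any(JS <= n):
        raise CompactionError("J_S <= n0S in seepage evaluation")
    pref = (params.K0_si / params.muFR) * (JS - n) / (1.0 - n)
    return -pref[..., None] * grad_p if pref.ndim else -pref * grad_p


def dissipation_rates(tau_neq: np.ndarray, w: np.ndarray, JS,
                      params: MaterialParameters) -> DissipationRates:
    """Viscous and porous dissipation power densities (both >= 0).

    ``Dv = tau_neq : tau_neq / (2 eta)`` (per unit reference volume) and
    ``Dp = (muFR/K0) [(1-n0S)/(J-n0S)] w.w`` (per unit current volume).
    """
    tau_neq = np.asarray(tau_neq, dtype=float)
    w = np.asarray(w, dtype=float)
    JS = np.asarray(JS, dtype=float)
    n = params.n0S
    if np.any(JS <= n):
        raise CompactionError("J_S <= n0S in dissipation evaluation")
    Dv = np.einsum("...ij,...ij->...", tau_neq, tau_neq) / (2.0 * params.eta)
    Dp = (params.muFR / params.K0_si) * (1.0 - n) / (JS - n) * np.einsum(
        "...i,...i->...", w, w
    )
    return DissipationRates(Dv=Dv if Dv.ndim else float(Dv),
                            Dp=Dp if Dp.ndim else float(Dp))


# -- stored-energy densities (used for global energy bookkeeping) -------------

def ogden_energy_density(F: np.ndarray, params: MaterialParameters):
    """Equilibrium Ogden strain-energy density per unit reference volume.

    ``W = sum_a [ mu/alpha (lambda_a^alpha - 1) - mu ln lambda_a ]`` whose
    principal Kirchhoff stresses are exactly ``mu (lambda_a^alpha - 1)``.
    """
    F = np.asarray(F, dtype=float)
    b = F @ np.swapaxes(F, -1, -2)
    lam2, _ = _spectral(b)
    lam = np.sqrt(np.clip(lam2, 1e-300, None))
    mu, al = params.mu_inf, params.alpha_inf
    W = (mu / al) * (lam ** al - 1.0) - mu * np.log(lam)
    return W.sum(axis=-1)


def volumetric_energy_density(JS, params: MaterialParameters):
    """Energy of the volumetric extension function, ``J U'(J) = tau_vol``."""
    JS = np.asarray(JS, dtype=float)
    n = params.n0S
    c = params.lambda_star * (1.0 - n) ** 2
    return c * ((JS - 1.0) / (1.0 - n) - np.log((JS - n) / (1.0 - n)))
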