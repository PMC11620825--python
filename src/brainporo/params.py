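"""Material parameters of the biphasic poro-viscoelastic tissue model.

The solid skeleton carries a one-term Ogden spring (equilibrium branch), an
optional Ogden--dashpot Maxwell branch (non-equilibrium branch) and a
volumetric extension function controlled by the first Lamé parameter
``lambda_star``.  The pore fluid interacts with the skeleton through a
Darcy-like law with initial intrinsic permeability ``K0``.

Units follow laboratory convention at the interface: moduli in Pa, viscosity
in Pa·s, permeability in mm² (converted to m² internally), geometry in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Mapping

MM2_TO_M2 = 1e-6  # 1 mm² = 1e-6 m²

#: Lower bound of admissible first Lamé parameters (Pa); below this the
#: volumetric extension function no longer stabilises the solid numerically.
LAMBDA_STAR_MIN = 10.0


@dataclass(frozen=True)
class MaterialParameters:
    """Full poro-viscoelastic parameter set.

    Parameters
    ----------
    mu_inf : float
        Equilibrium Ogden shear modulus (Pa).  Brain-tissue fits are negative
        together with ``alpha_inf`` so that ``mu_inf * alpha_inf > 0``.
    alpha_inf : float
        Equilibrium Ogden nonlinearity (dimensionless).
    mu_1 : float
        Non-equilibrium (Maxwell branch) Ogden shear modulus (Pa).  Setting
        ``mu_1 = 0`` switches the Maxwell branch off and reduces the model to
        nonlinear poroelasticity.
    alpha_1 : float
        Non-equilibrium Ogden nonlinearity (dimensionless).
    eta : float
        Solid viscosity of the Maxwell dashpot (Pa·s), > 0.
    lambda_star : float
        First Lamé parameter of the solid (Pa), >= 10 Pa.  Controls the
        volumetric extension function and hence how strongly volume changes of
        the mixture are penalised.
    K0 : float
        Initial intrinsic permeability (mm²), isotropic, > 0.
    n0S : float
        Initial solid volume fraction, in (0, 1).  The Jacobian of the solid
        deformation is admissible only for ``J_S > n0S`` (compaction point).
    muFR : float
        Effective pore-fluid shear viscosity (Pa·s), > 0.
    """

    mu_inf: float
    alpha_inf: float
    mu_1: float = 0.0
    alpha_1: float = 0.0
    eta: float = 1.0
    lambda_star: float = 100.0
    K0: float = 1e-7
    n0S: float = 0.75
    muFR: float = 0.89

    def __post_init__(self) -> None:
        if not (self.eta > 0.0):
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if not (self.muFR > 0.0):
            raise ValueError(f"muFR must be > 0, got {self.muFR}")
        if not (self.K0 > 0.0):
            raise ValueError(f"K0 must be > 0, got {self.K0}")
        if not (0.0 < self.n0S < 1.0):
            raise ValueError(f"n0S must lie in (0, 1), got {self.n0S}")
        if self.lambda_star < LAMBDA_STAR_MIN:
            raise ValueError(
                f"lambda_star must be >= {LAMBDA_STAR_MIN} Pa, got {self.lambda_star}"
            )
        if not (self.mu_inf * self.alpha_inf > 0.0):
            raise ValueError(
                "mu_inf * alpha_inf must be > 0 (positive ground-state shear "
                f"stiffness), got mu_inf={self.mu_inf}, alpha_inf={self.alpha_inf}"
            )
        if self.mu_1 != 0.0 and not (self.mu_1 * self.alpha_1 > 0.0):
            raise ValueError(
                "mu_1 * alpha_1 must be > 0 for an active Maxwell branch, "
                f"got mu_1={self.mu_1}, alpha_1={self.alpha_1}"
            )

    @property
    def K0_si(self) -> float:
        """Intrinsic permeability in m²."""
        return self.K0 * MM2_TO_M2

    @property
    def is_poroelastic(self) -> bool:
        """True when the Maxwell branch is switched off (mu_1 == 0)."""
        return self.mu_1 == 0.0

    # -- flat key-value (de)serialisation -------------------------------------
    _CONFIG_KEYS = (
        "mu_inf", "alpha_inf", "mu_1", "alpha_1", "eta",
        "lambda_star", "K0_mm2", "n0S", "muFR",
    )

    def to_config(self) -> dict:
        """Flat key-value mapping; permeability exported as ``K0_mm2``."""
        d = asdict(self)
        d["K0_mm2"] = d.pop("K0")
        return {k: d[k] for k in self._CONFIG_KEYS}

    @classmethod
    def from_config(cls, cfg: Mapping[str, float]) -> "MaterialParameters":
        cfg = dict(cfg)
        if "K0_mm2" in cfg:
            cfg["K0"] = cfg.pop("K0_mm2")
        unknown = set(cfg) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown material-parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in cfg.items()})

    def replace(self, **changes) -> "MaterialParameters":
        if "K0_mm2" in changes:
            changes["K0"] = changes.pop("K0_mm2")
        return replace(self, **changes)


#: Poroelastic visual-cortex Ogden parameters used throughout the simulation
#: studies (equilibrium branch only).
CORTEX_OGDEN = dict(mu_inf=-43.8, alpha_inf=-12.76)


def cortex_study_parameters(lambda_star: float = 1e4, K0: float = 1e-7,
                            **extra) -> MaterialParameters:
    """Poroelastic parameter set of the cyclic/relaxation simulation studies."""
    return MaterialParameters(
        mu_inf=CORTEX_OGDEN["mu_inf"], alpha_inf=CORTEX_OGDEN["alpha_inf"],
        mu_1=0.0, alpha_1=0.0, lambda_star=lambda_star, K0=K0,
        n0S=0.75, muFR=0.89, **extra,
    )
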