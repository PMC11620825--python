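# brainporo

Finite-strain **biphasic poro-viscoelastic mechanics of brain tissue**:
a constitutive core (one-term Ogden equilibrium and Maxwell branches, a
volumetric extension function with a compaction point, Darcy-like seepage),
a mixed displacement–pressure (Q2Q1 hexahedral) finite-element solver for
cylindrical specimen experiments, the cyclic and relaxation loading
protocols with their derived observables, a synthetic-experiment generator,
and inverse material-parameter identification with a Model/Results fitting
interface.

The package is aimed at tissue biomechanists who want to *explore what the
parameters of a biphasic model actually do* — in particular the interplay
between the first Lamé parameter λ\*, which penalises volume change of the
mixture, and the intrinsic permeability K0, which controls how fast pore
fluid can actually move — and at fitting such models to stress–time records
from unconfined compression/tension experiments.

## The model in one paragraph

Brain tissue is modelled as an incompressible solid skeleton saturated by
incompressible interstitial fluid; the mixture changes volume only through
fluid flow, and the solid Jacobian is bounded by the compaction point
J = n0S where all pores are closed. The Kirchhoff stress is

τ = τ_eq + τ_neq + τ_vol − p J **I**,

with spectral one-term Ogden branches (β_a = μ∞[λ_a^α∞ − 1] on the total
stretches for the equilibrium part; the deviatoric analogue on the
isochoric elastic stretches of the internal variable b_e for the Maxwell
part, evolving as −L_v(b_e) b_e⁻¹ = τ_neq/η), the volumetric extension
function τ_vol = λ\*(1−n0S)²[J/(1−n0S) − J/(J−n0S)] **I**, and the pore
pressure p. The seepage velocity follows a Darcy-like law with a
deformation-dependent permeability that vanishes at compaction. Both
dissipation channels — viscous τ:τ/(2η) and porous (μFR/K0)·w·w-type — are
non-negative by construction. See `docs/methods.md` for the full account.

## Worked example

Fast-ramp compression relaxation of a visual-cortex specimen (radius 4 mm,
height 3.4 mm, 15 % compression at 2.5 /s, 600 s hold, drained hull),
poroelastic parameters μ∞ = −43.8 Pa, α∞ = −12.76, n0S = 0.75,
μFR = 0.89 Pa·s, K0 = 1e−7 mm², λ\* = 1e4 Pa:

```python
from brainporo import relaxation_study

study = relaxation_study(lambda_star=1e4, K0=1e-7, radius=4.0,
                         resolution=(3, 3, 4))
m = study.metrics
print(f"peak stress        {m.peak_stress:8.1f} Pa")
print(f"equilibrium stress {m.equilibrium_stress:8.1f} Pa")
print(f"relaxation         {m.relaxation_fraction:8.1f} %")
```

prints (about two minutes on one core):

```
peak stress         -1200.8 Pa
equilibrium stress  -1084.8 Pa
relaxation               9.7 %
```

During the 2.5 /s ramp the fluid cannot escape, so the specimen responds as
a nearly incompressible elastic body and the glued platens make the squat
cylinder much stiffer than a frictionless one; during the hold, fluid
drains through the hull and the stress relaxes toward the drained skeleton
response. At λ\* = 1e4 Pa the volumetric extension function suppresses
volume change, so only ~10 % of the peak stress relaxes away; dropping
λ\* to 1e2 Pa, or enlarging the radius to 8 mm, increases both the fluid
flow and the relaxed fraction. The permeability K0 rescales the relaxation
clock but not the relaxed amount.

Fitting works through the Model/Results interface:

```python
from brainporo import PoroViscoelasticTissueModel, make_cyclic_protocol

proto = make_cyclic_protocol(0.15, n_cycles=1, rate=0.01, height=3.4)
model = PoroViscoelasticTissueModel.from_csv(["record_00.csv"], [proto],
                                             mode="poroelastic",
                                             lambda_star=1e2)
res = model.fit(seed=0, n_starts=3)
print(res.summary())           # estimates, std errors, RMSE, K0 spread
```

A thin CLI mirrors the two workflows:
`brainporo simulate --config cfg.json --protocol relax-compression --out out/`
and `brainporo fit --config cfg.json --targets data/ --mode poroelastic
--lambda-star 100 --out report.json`.

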