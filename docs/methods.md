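# Methods

## The model

`brainporo` treats brain tissue as a saturated biphasic mixture in the sense
of the Theory of Porous Media: an intrinsically incompressible viscoelastic
solid skeleton (cells, vessels, extracellular matrix) and an intrinsically
incompressible pore fluid occupy every material point with volume fractions
`nS + nF = 1`. The mixture changes volume only by fluid in/outflow, so the
Jacobian of the solid deformation `J_S = det F_S` is bounded below by the
initial solid fraction `n0S`: at `J_S = n0S` all pores are closed (the
compaction point) and the volumetric stress diverges.

The Kirchhoff stress is assembled additively,

    tau = tau_eq + tau_neq + tau_vol - p J_S I,

with

- **Equilibrium branch**: one-term Ogden in the principal stretches of
  `b_S = F_S F_S^T`, principal values `mu_inf (lambda_a^alpha_inf - 1)`.
  It is evaluated on the *total* stretches, so it carries both isochoric
  and volumetric content.
- **Non-equilibrium (Maxwell) branch**: one-term Ogden on the *isochoric*
  elastic stretches of the internal variable `b_e` (elastic left
  Cauchy–Green tensor of the multiplicative split `F = F_e F_v`), with the
  deviatoric principal form that makes its principal values sum to zero.
  Its evolution law `-L_v(b_e) b_e^{-1} = tau_neq / eta` gives the
  non-negative viscous dissipation `D_v = tau_neq : tau_neq / (2 eta)`.
- **Volumetric extension function**:
  `tau_vol = lambda* (1-n0S)^2 [ J/(1-n0S) - J/(J-n0S) ] I`; zero at
  `J = 1`, divergent at compaction. `lambda*` acts like a volumetric
  stiffness of the drained skeleton: large values suppress volume change
  and hence every porous effect, without touching the permeability.
- **Fluid**: hydrostatic `-p J_S I`, with a Darcy-like seepage law
  `w = -(K0/muFR) (J-n0S)/(1-n0S) grad p` whose deformation-dependent
  prefactor closes the pores at compaction, and porous dissipation
  `D_p = (muFR/K0) (1-n0S)/(J-n0S) |w|^2 >= 0`.

Quasi-statics without body forces or tractions gives the two weak
statements solved monolithically for `(u, p)`: the momentum balance
`int grad(du) : tau dV0 = 0` and the fluid mass balance
`int dp Jdot dV0 - int grad(dp) . w J dV0 = 0` (spatial gradients; no flux
through undrained boundaries as natural condition).

## Parameters

| name | meaning | unit | default / study value |
|------|---------|------|----------------------|
| `mu_inf`, `alpha_inf` | equilibrium Ogden pair (`mu*alpha > 0`; brain fits are negative–negative) | Pa, – | −43.8 Pa, −12.76 (visual-cortex poroelastic studies) |
| `mu_1`, `alpha_1` | Maxwell-branch Ogden pair; `mu_1 = 0` switches the model to pure poroelasticity | Pa, – | 0 (studies) |
| `eta` | solid viscosity of the Maxwell dashpot | Pa·s | — |
| `lambda_star` | first Lamé parameter of the volumetric extension function; admissible from 10 Pa | Pa | studied at 1e2…1e4 |
| `K0` | initial intrinsic permeability, isotropic | mm² (1e−6 m²) | studied at 1e−6…1e−8 |
| `n0S` | initial solid volume fraction | – | 0.75 |
| `muFR` | effective pore-fluid shear viscosity | Pa·s | 0.89 |

Geometry: cylindrical specimens, radius 4 mm (studies also 6 and 8 mm),
height 3.4 mm (visual cortex) or 5.0 mm (corona radiata). Internally all
computations are SI (m, s, Pa); the interfaces take mm and mm².

## Discretisation

A quarter cylinder is meshed with a butterfly (O-grid) layout of
triquadratic-displacement / trilinear-continuous-pressure (Q2Q1,
Taylor–Hood-type) hexahedra under 3×3×3 Gauss quadrature; the default
`4/4/8` block resolution yields the 384-element discretisation of the r =
4 mm specimens. Mid-edge hull nodes are placed exactly on the cylinder, so
the quadratic geometry tracks the curved boundary (volume error < 1e−5).
The pressure space is chosen continuous for inf-sup stability with
standard assembly; a discontinuous per-element pressure would alter
pointwise fields near the hull but not the integral observables reported
here.

Boundary conditions reproduce the glued-specimen protocol: bottom fixed,
top fixed laterally and driven axially, symmetry (zero normal
displacement) on the flat faces, and `p = 0` strongly on the hull from t =
0 — the hull is the only drained surface. Time integration is backward
Euler (including `Jdot`), with adaptive stepping: each protocol segment
starts at 1/40 of its duration (a hold after a fast ramp inherits the
running step instead), cuts ×0.5 on failure, grows ×1.2 after two clean
steps, clamped to [1e−4 s, `dt_max`].

The monolithic Newton iteration uses a consistent tangent built from
forward differences (step 1e−7) of the *smooth* stress and flux kernels
with respect to `F`, plus analytic expressions for the volumetric-barrier,
fluid-stress, volume-rate and pressure couplings — the barrier curvature
near compaction is far too large for finite differences. The linearised
system is factorised directly (SuperLU). Two robustness devices matter in
the strongly nonlinear runs (large radii, small `lambda*`): the singular
terms are evaluated with a C1 linear extension below `J = n0S + 1e-3` so
that intermediate Newton iterates may graze the barrier (strict
admissibility `J > n0S` is enforced at step acceptance), and each update
is backtracked if it would push a quadrature point deep past the barrier.
A frozen-tangent (modified Newton) shortcut reuses the factorisation while
the residual contracts by ≥ 4× per iteration. Convergence is declared at
1e−6 relative residual (momentum and mass blocks separately) or at
working-precision increments.

The viscous evolution law is integrated by the exponential-map backward
Euler return mapping in principal logarithmic elastic strain: trial state
`b_tr = f b_e_old f^T` with the relative deformation gradient
`f = F_new F_old^{-1}`, then a local Newton (analytic 3×3 Jacobian,
tolerance 1e−10, ≤ 30 iterations) on
`eps_a = eps_a^tr - (dt/2 eta) beta_a(eps)`. Because the `beta_a` are
deviatoric the update preserves `sum_a eps_a`, i.e. the viscous flow is
exactly isochoric and `b_e` stays symmetric positive definite. Against
dense ODE integration of the continuous law the stepped update converges
first order; at the step counts used in the tests the trajectory error in
`tau_neq` is below 0.5 %.

## Observables

Nominal stress is the axial reaction on the (quarter-model) top face over
the (quarter) undeformed cross-section, compression negative. Relaxation
read-outs: peak = stress at the last ramp sample; equilibrium = mean over
the final 1 % of the hold; relaxation fraction =
`100 (|peak| - |equilibrium|)/|peak|`. Lateral displacement = maximum
radial displacement over the hull ring at half height. Dissipation totals
integrate `D_v` over the reference volume and `D_p` over the current
volume (`D_p J dV0`) — exactly the weights for which external work equals
stored-energy change plus total dissipation; the cyclic energy-budget test
closes this identity within 5 %.

## Inverse identification

The objective is the pooled RMSE (Pa) between simulated and recorded
nominal stress, minimised by bound-constrained trust-region-reflective
least squares. The Jacobian is built by finite differences with a
*relative step of 0.01*: adaptive time stepping makes the residual only
piecewise smooth in the parameters, and steps near machine precision
differentiate solver noise instead of the model. `K0` is fitted as
`log10(K0/mm^2)` because candidate values span seven orders of magnitude;
moduli, nonlinearities and `eta` are fitted linearly on the negative
(`mu`, `alpha` < 0) branch with bounds `|mu| in [1, 1e4]` Pa, `|alpha| in
[0.5, 30]`, `eta in [10, 1e5]` Pa·s, `lambda* in [10, 1e5]` Pa,
`log10 K0 in [-12, -3]`. Optional preprocessing applies a centred moving
average (default window 5 samples) and Ramer–Douglas–Peucker thinning
(default 0.5 Pa) to the stress channel. Multi-start initialisation draws
from a seeded Latin hypercube (default 5 starts) and the spread of the
fitted `log10 K0` across starts is reported, never collapsed — the
six-parameter set is known not to be uniquely identifiable from a single
cycle. Forward-solver failures at trial points return a large penalty so
the optimiser can continue. Standard errors in the Results object are the
usual Gauss–Newton linearisation `s^2 (J^T J)^{-1}`; treat them as local
curvatures, not honest uncertainties, for the reasons above.

## Synthetic data

The generator runs the forward model for each protocol, resamples the
stress to an acquisition grid (10 Hz on ramps/cycles, 1 Hz on holds —
enough to resolve the 0.06 s ramp without bloating hold files) and adds
i.i.d. Gaussian noise (default sigma = 5 Pa) to the stress channel only,
bit-reproducibly per seed. It emulates the *statistical shape* of
rheometer records — piecewise-linear displacement protocols, nominal
stress with hysteresis and compression–tension asymmetry, additive
noise — not their physiology: no cycle-to-cycle conditioning (Mullins-type
softening), no drift, no heteroscedasticity. Tests that pass on these
records therefore validate the pipeline (solver, observables, optimiser),
not the constitutive model's fidelity to real tissue.

## Problem sizes and numerical choices

The working resolutions are block subdivisions of the butterfly mesh:
`(3,3,4)` (108 elements, ~3.6k unknowns) for the r = 4 mm
relaxation-fraction studies, `(3,3,2)` (54 elements) for the r = 8 mm
runs and for the bulge and dissipation-timing read-outs, and the
3-element `(1,1,1)` mesh inside fitting loops, where target and fit share
the same mesh so discretisation bias cancels. These sizes keep every
study minutes-scale on a single core. Convergence behaviour: the r = 4 mm
relaxation fraction at lambda* = 1e4 Pa moves 13.5 % (24 el) -> 9.7 %
(108 el) -> 10.1 % (at 48 in-plane cells x 3 layers); the r = 8 mm
fractions move by 2-3 percentage points between 54 and 108 elements
(49.1 -> 46.5 % at lambda* = 1e4 Pa). Headline runs use `dt_max = 20 s`
during holds and `0.5 s` during cycles.

## Known limitations

- **Drainage time scale vs. the printed study values.** With the stated
  study parameters, the pore-pressure diffusivity is of order
  `c ≈ (K0/muFR)(lambda* + tangent stiffness)`; at K0 = 1e−7 mm² this
  gives equilibration times of several thousand seconds for r ≥ 4 mm at
  lambda* = 1e2 Pa — long compared to the 600 s hold. Our simulations
  (validated to <1 % against the linear consolidation series) therefore
  show the low-`lambda*` relaxation still in progress at 600 s, and the
  600 s relaxation fractions at low `lambda*` fall well short of the
  values the original study reports at equal `K0`. The K0-independence of
  the *equilibrium* relaxation amount, the ordering in radius and
  `lambda*`, the near-vanishing bulge at low `lambda*` at equilibrium, and
  the high-`lambda*` fractions are all reproduced.
- The model cannot represent conditioning between cycles; fits pool all
  protocols unweighted unless per-protocol weights are configured.
- Anisotropic permeability, compressible constituents, temperature and
  damage are out of scope.
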