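"""Shared fixtures.

The expensive finite-element studies are session-scoped and shared between
the behavioural tests and the acceptance suite, so each configuration is
simulated exactly once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from brainporo.fem import SolverControls
from brainporo.params import MaterialParameters, cortex_study_parameters
from brainporo.studies import cyclic_study, relaxation_study

#: resolution used by the specimen-level studies in the test suite
STUDY_RESOLUTION = (3, 3, 2)
STUDY_CONTROLS = SolverControls(dt_max=20.0)


@pytest.fixture(scope="session")
def cortex_poro():
    """Poroelastic visual-cortex parameter set of the simulation studies."""
    return cortex_study_parameters()


@pytest.fixture(scope="session")
def table5_cortex():
    """Full poro-viscoelastic visual-cortex fit (cycles + relaxations)."""
    return MaterialParameters(mu_inf=-30.7, alpha_inf=-11.9, mu_1=-45.9,
                              alpha_1=-14.4, eta=6770.0, lambda_star=100.0,
                              K0=4.18e-9)


@pytest.fixture(scope="session")
def relaxation_grid():
    """Compression-relaxation runs (ramp 2.5/s to 15 %, hold 600 s,
    K0 = 1e-7 mm2) over radius x lambda*: the size/volumetric study."""
    out = {}
    for r in (4.0, 8.0):
        for lam in (1e4, 1e2):
            out[(r, lam)] = relaxation_study(
                lambda_star=lam, K0=1e-7, radius=r,
                resolution=STUDY_RESOLUTION, controls=STUDY_CONTROLS)
    return out


@pytest.fixture(scope="session")
def k0_relaxations():
    """Same protocol at fixed lambda* = 1e2 Pa, r = 4 mm, two
    permeabilities.  The hold is scaled with 1/K0 (600 s at 1e-6 mm2,
    6000 s at 1e-7 mm2) so both runs reach their relaxed plateau: the
    permeability rescales the relaxation clock, and the comparison of the
    relaxed *amounts* is only meaningful at the plateau."""
    out = {}
    for K0, hold in ((1e-6, 600.0), (1e-7, 6000.0)):
        out[K0] = relaxation_study(lambda_star=1e2, K0=K0, radius=4.0,
                                   hold=hold, resolution=STUDY_RESOLUTION,
                                   controls=SolverControls(dt_max=50.0))
    return out


@pytest.fixture(scope="session")
def lateral_runs():
    """Relaxation runs at K0 = 1e-6 mm2 for the residual-bulge study."""
    ctrl = SolverControls(dt_max=30.0)
    out = {}
    for r in (4.0, 6.0, 8.0):
        out[(r, 1e4)] = relaxation_study(lambda_star=1e4, K0=1e-6, radius=r,
                                         resolution=STUDY_RESOLUTION,
                                         controls=ctrl)
    out[(8.0, 1e2)] = relaxation_study(lambda_star=1e2, K0=1e-6, radius=8.0,
                                       resolution=STUDY_RESOLUTION,
                                       controls=ctrl)
    return out


@pytest.fixture(scope="session")
def cyclic_run():
    """First poroelastic loading cycle at lambda* = 1e4 Pa, K0 = 1e-7 mm2
    (the dissipation-rate timing configuration)."""
    return cyclic_study(lambda_star=1e4, K0=1e-7, n_cycles=1,
                        resolution=STUDY_RESOLUTION,
                        controls=SolverControls(dt_max=1.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
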