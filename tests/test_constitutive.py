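"""Pointwise constitutive laws: spectral stresses, viscous evolution,
seepage and dissipation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import brainporo.constitutive as cc
from brainporo.exceptions import (CompactionError, InvalidDeformationError,
                                  InvalidStateError)
from brainporo.params import MaterialParameters, cortex_study_parameters


@pytest.fixture(scope="module")
def poro():
    return cortex_study_parameters()


@pytest.fixture(scope="module")
def visco():
    # cyclic poro-viscoelastic cortex fit at lambda* = 1e2 Pa
    return MaterialParameters(mu_inf=-1010.0, alpha_inf=-2.78, mu_1=-1170.0,
                              alpha_1=-6.31, eta=5380.0, lambda_star=100.0,
                              K0=1.86e-7)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    return q * np.sign(np.linalg.det(q))


class TestEquilibriumStress:
    def test_reference_state_is_stress_free(self, poro):
        assert np.allclose(cc.equilibrium_stress(np.eye(3), poro), 0.0)

    def test_uniaxial_principal_value(self, poro):
        # axial stretch 0.85 with cortex Ogden parameters
        F = np.diag([1.05, 1.1, 0.85])
        tau = cc.equilibrium_stress(F, poro)
        expected = -43.8 * (0.85 ** -12.76 - 1.0)
        assert tau[2, 2] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-304.6, abs=0.1)

    def test_objectivity_under_rotation(self, poro, rng):
        for _ in range(20):
            F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.05:
                continue
            Q = random_rotation(rng)
            t1 = cc.equilibrium_stress(Q @ F, poro)
            t2 = Q @ cc.equilibrium_stress(F, poro) @ Q.T
            assert np.allclose(t1, t2, rtol=1e-10, atol=1e-8)

    def test_invalid_deformation_rejected(self, poro):
        with pytest.raises(InvalidDeformationError):
            cc.equilibrium_stress(np.full((3, 3), np.nan), poro)


class TestNonequilibriumStress:
    def test_identity_gives_zero(self, visco):
        assert np.allclose(cc.nonequilibrium_stress(np.eye(3), visco), 0.0)

    def test_principal_values_are_deviatoric(self, visco, rng):
        for _ in range(20):
            L = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
            be = L @ L.T
            tau = cc.nonequilibrium_stress(be, visco)
            assert abs(np.trace(tau)) < 1e-8 * (1 + np.abs(tau).max())

    def test_matches_energy_derivative(self, visco):
        # tau_a = d W1 / d eps_a of the isochoric one-term Ogden energy
        lam = 1.1
        be = np.diag([lam ** 2, 1 / lam, 1 / lam])
        tau = cc.nonequilibrium_stress(be, visco)

        mu1, a1 = visco.mu_1, visco.alpha_1

        def W1(eps):
            lt = np.exp(eps - np.mean(eps))
            return (mu1 / a1) * np.sum(lt ** a1 - 1.0)

        eps0 = 0.5 * np.log(np.diag(be))
        h = 1e-6
        for a in range(3):
            de = np.zeros(3)
            de[a] = h
            fd = (W1(eps0 + de) - W1(eps0 - de)) / (2 * h)
            assert tau[a, a] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_non_spd_rejected(self, visco):
        with pytest.raises(InvalidStateError):
            cc.nonequilibrium_stress(np.diag([1.0, -0.5, 1.0]), visco)


class TestVolumetricStress:
    def test_zero_at_unit_jacobian(self, poro):
        assert cc.volumetric_stress(1.0, poro) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_value(self, poro):
        p = poro.replace(lambda_star=1e3)
        # 62.5 * (3.6 - 6.0) with n0S = 0.75
        assert cc.volumetric_stress(0.9, p) == pytest.approx(-150.0, rel=1e-12)

    def test_diverges_towards_compaction(self, poro):
        js = np.linspace(0.7501, 0.85, 50)
        v = cc.volumetric_stress(js, poro)
        assert np.all(np.diff(v) > 0)  # monotone increasing in J
        assert cc.volumetric_stress(0.750001, poro) < -1e6

    def test_compaction_point_rejected(self, poro):
        with pytest.raises(CompactionError):
            cc.volumetric_stress(0.74, poro)


class TestTotalStress:
    def test_reference_state_zero(self, poro):
        s = cc.total_stress(cc.QuadraturePointState.reference(), poro)
        assert np.allclose(s.tau_total, 0.0)

    def test_pure_pressure_state(self, poro):
        st = cc.QuadraturePointState(F=np.eye(3), be_e=np.eye(3), JS=1.0,
                                     p=100.0)
        s = cc.total_stress(st, poro)
        assert np.allclose(s.tau_total, -100.0 * np.eye(3))

    def test_poroelastic_reduction_ignores_be(self, poro, rng):
        # with mu_1 = 0 the response must not depend on the internal variable
        F = np.diag([0.9, 1.05, 1.02])
        L = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        st1 = cc.QuadraturePointState(F=F, be_e=np.eye(3),
                                      JS=np.linalg.det(F), p=50.0)
        st2 = cc.QuadraturePointState(F=F, be_e=L @ L.T,
                                      JS=np.linalg.det(F), p=50.0)
        assert np.allclose(cc.total_stress(st1, poro).tau_total,
                           cc.total_stress(st2, poro).tau_total)

    def test_decomposition_sums(self, visco, rng):
        L = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        st = cc.QuadraturePointState(F=L, be_e=np.eye(3) * 1.1,
                                     JS=np.linalg.det(L), p=10.0)
        s = cc.total_stress(st, visco)
        assert np.allclose(s.tau_total,
                           s.tau_eq + s.tau_neq + s.tau_vol + s.tau_fluid)


class TestViscousUpdate:
    def test_fixed_point_at_zero_stress(self, visco):
        be = np.eye(3)
        be2, tau = cc.update_viscous_state(np.eye(3), be, np.eye(3), 0.5,
                                           visco)
        assert np.allclose(be2, be)
        assert np.allclose(tau, 0.0)

    def test_elastic_limit_large_viscosity(self, visco, rng):
        stiff = visco.replace(eta=1e15)
        F_old = np.eye(3)
        F_new = np.diag([1.1, 0.95, 0.97])
        be_old = np.eye(3)
        be2, _ = cc.update_viscous_state(F_new, be_old, F_old, 1.0, stiff)
        b_trial = F_new @ be_old @ F_new.T
        assert np.allclose(be2, b_trial, rtol=1e-10)

    def test_stress_relaxes_monotonically_to_zero(self, visco):
        F = np.diag([0.9, 1.03, 1.08])
        be = F @ F.T
        norms = []
        for _ in range(400):
            be, tau = cc.update_viscous_state(F, be, F, 0.1, visco)
            norms.append(np.linalg.norm(tau))
        norms = np.asarray(norms)
        assert np.all(np.diff(norms) <= 1e-12)
        assert norms[-1] < 1e-3 * norms[0]

    def test_viscous_flow_is_isochoric(self, visco, rng):
        # det(be) relative to the trial state is preserved by the return map
        F_old = np.eye(3)
        be = np.eye(3)
        F_new = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
        be2, _ = cc.update_viscous_state(F_new, be, F_old, 0.3, visco)
        b_tr = F_new @ be @ F_new.T
        assert np.linalg.det(be2) == pytest.approx(np.linalg.det(b_tr),
                                                   rel=1e-10)

    def test_matches_dense_ode_integration(self, visco, rng):
        """Backward-Euler exponential map vs. high-accuracy integration of
        the continuous evolution law on a smooth loading history."""
        A = 0.08 * rng.standard_normal((3, 3))
        B = 0.08 * rng.standard_normal((3, 3))

        def Fof(t):
            return np.eye(3) + A * np.sin(0.8 * t) + B * (1 - np.cos(0.5 * t))

        def rhs(t, y):
            be = y.reshape(3, 3)
            F = Fof(t)
            dF = (Fof(t + 1e-6) - Fof(t - 1e-6)) / 2e-6
            l = dF @ np.linalg.inv(F)
            tau = cc.nonequilibrium_stress(0.5 * (be + be.T), visco)
            return (l @ be + be @ l.T - (tau @ be) / visco.eta).ravel()

        T = 4.0
        sol = solve_ivp(rhs, [0, T], np.eye(3).ravel(), rtol=1e-10,
                        atol=1e-12)
        be_ref = sol.y[:, -1].reshape(3, 3)
        tau_ref = cc.nonequilibrium_stress(0.5 * (be_ref + be_ref.T), visco)

        ts = np.linspace(0.0, T, 801)
        be = np.eye(3)
        for t0, t1 in zip(ts[:-1], ts[1:]):
            be, tau = cc.update_viscous_state(Fof(t1), be, Fof(t0), t1 - t0,
                                              visco)
        err = np.linalg.norm(tau - tau_ref) / np.linalg.norm(tau_ref)
        assert err < 5e-3


class TestSeepageAndDissipation:
    def test_zero_gradient_zero_flow(self, poro):
        assert np.allclose(cc.seepage_velocity(np.zeros(3), 1.0, poro), 0.0)

    def test_darcy_magnitude_with_unit_conversion(self, poro):
        w = cc.seepage_velocity(np.array([1000.0, 0.0, 0.0]), 1.0, poro)
        # K0 = 1e-7 mm2 = 1e-13 m2, muFR = 0.89 Pa s
        assert w[0] == pytest.approx(-(1e-13 / 0.89) * 1000.0, rel=1e-12)
        assert w[1] == w[2] == 0.0

    def test_flow_shuts_down_at_compaction(self, poro):
        g = np.array([1e5, 0.0, 0.0])
        w_near = cc.seepage_velocity(g, poro.n0S + 1e-9, poro)
        assert np.linalg.norm(w_near) < 1e-8 * np.linalg.norm(
            cc.seepage_velocity(g, 1.0, poro))

    def test_viscous_dissipation_value(self):
        p = MaterialParameters(mu_inf=-1010.0, alpha_inf=-2.78, mu_1=-1170.0,
                               alpha_1=-6.31, eta=5380.0)
        a = 100.0
        tau = np.diag([a, -a / 2, -a / 2])
        d = cc.dissipation_rates(tau, np.zeros(3), 1.0, p)
        assert d.Dv == pytest.approx(1.5 * a ** 2 / (2 * 5380.0), rel=1e-12)
        assert d.Dp == 0.0

    def test_dissipation_nonnegative_on_random_states(self, poro, rng):
        """Thermodynamic consistency over a thousand random admissible
        states (positivity of both dissipation powers)."""
        p = poro.replace(mu_1=-45.9, alpha_1=-14.4, eta=6770.0)
        n = 1000
        tau = rng.standard_normal((n, 3, 3)) * 200.0
        tau = 0.5 * (tau + np.swapaxes(tau, -1, -2))
        w = rng.standard_normal((n, 3)) * 1e-6
        JS = rng.uniform(p.n0S + 1e-3, 1.3, size=n)
        d = cc.dissipation_rates(tau, w, JS, p)
        assert np.all(d.Dv >= 0.0)
        assert np.all(d.Dp >= 0.0)
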