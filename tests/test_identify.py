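"""Signal preprocessing and the RMSE identification machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainporo.identify import (FitSpec, fit_parameters, moving_average,
                                objective_rmse, preprocess_signal,
                                rdp_simplify)
from brainporo.params import MaterialParameters
from brainporo.protocols import ExperimentRecord, LoadProtocol


class TestMovingAverage:
    def test_window_one_is_identity(self, rng):
        y = rng.standard_normal(30)
        assert np.allclose(moving_average(y, 1), y)

    def test_constant_preserved(self):
        assert np.allclose(moving_average(np.full(20, 3.0), 5), 3.0)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), 4)       # even
        with pytest.raises(ValueError):
            moving_average(np.zeros(3), 5)        # longer than series


class TestRDP:
    def test_zero_epsilon_keeps_everything(self, rng):
        t = np.arange(50.0)
        y = rng.standard_normal(50)
        assert len(rdp_simplify(t, y, 0.0)) == 50

    def test_collinear_collapses_to_endpoints(self):
        t = np.linspace(0, 10, 37)
        y = 2.0 * t - 1.0
        idx = rdp_simplify(t, y, 1e-9)
        assert list(idx) == [0, 36]

    def test_triangle_apex_threshold(self):
        # apex at perpendicular distance 1 from the base chord
        t = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 0.0])
        assert list(rdp_simplify(t, y, 0.5)) == [0, 1, 2]
        assert list(rdp_simplify(t, y, 1.5)) == [0, 2]

    @given(st.lists(st.floats(-100.0, 100.0), min_size=3, max_size=40),
           st.floats(1e-3, 10.0))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_structural_invariants(self, ys, eps):
        """Kept indices are strictly increasing, include both endpoints,
        and collapse to the endpoints when the tolerance dominates every
        deviation from the single chord."""
        t = np.arange(len(ys), dtype=float)
        y = np.asarray(ys)
        idx = rdp_simplify(t, y, eps)
        assert idx[0] == 0 and idx[-1] == len(ys) - 1
        assert np.all(np.diff(idx) > 0)
        big = rdp_simplify(t, y, 300.0)
        assert list(big) == [0, len(ys) - 1]

    def test_matches_brute_force_on_random_polyline(self, rng):
        """Every dropped point must lie within epsilon of the simplified
        polyline (checked against a brute-force distance computation)."""
        t = np.sort(rng.uniform(0, 10, 60))
        y = np.cumsum(rng.standard_normal(60))
        eps = 0.8
        idx = rdp_simplify(t, y, eps)
        # piecewise check: each original point vs its covering segment
        for k in range(len(t)):
            j = np.searchsorted(idx, k)
            if j < len(idx) and idx[j] == k:
                continue  # kept
            i0, i1 = idx[j - 1], idx[j]
            p0 = np.array([t[i0], y[i0]])
            p1 = np.array([t[i1], y[i1]])
            v = p1 - p0
            u = np.array([t[k], y[k]]) - p0
            d = abs(v[0] * u[1] - v[1] * u[0]) / np.linalg.norm(v)
            assert d <= eps + 1e-12


class TestPreprocess:
    def test_reduces_points_and_keeps_time_monotone(self, rng):
        t = np.linspace(0, 60, 600)
        s = -300 * np.sin(t / 10) + rng.normal(0, 2.0, 600)
        rec = ExperimentRecord(t, -0.5 * np.sin(t / 10), s)
        out = preprocess_signal(rec, window=5, epsilon=2.0)
        assert len(out) < len(rec)
        assert np.all(np.diff(out.t) >= 0)

    def test_zero_epsilon_keeps_all_samples(self, rng):
        t = np.linspace(0, 10, 100)
        rec = ExperimentRecord(t, np.zeros(100),
                               rng.standard_normal(100))
        out = preprocess_signal(rec, window=3, epsilon=0.0)
        assert len(out) == 100


class _LinearForward:
    """Cheap stand-in forward model: stress linear in the displacement with
    stiffness mu_inf (for objective/optimizer unit tests)."""

    def __call__(self, params, protocol):
        t = np.linspace(0, protocol.duration, 80)
        d = protocol.displacement(t)
        return ExperimentRecord(t, d, params.mu_inf * 10.0 * d, "simulated")


@pytest.fixture
def toy_setup():
    proto = LoadProtocol(((0.0, 0.0), (10.0, -0.5), (20.0, 0.0)))
    base = MaterialParameters(mu_inf=-50.0, alpha_inf=-5.0)
    forward = _LinearForward()
    target = forward(base, proto)
    spec = FitSpec(free=("mu_inf",), base=base.replace(mu_inf=-80.0),
                   protocols=(proto,))
    return spec, base, forward, target


class TestObjective:
    def test_self_consistency_zero(self, toy_setup):
        spec, base, forward, target = toy_setup
        assert objective_rmse(base, spec, [target], forward) == \
            pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_offset_rmse(self, toy_setup):
        spec, base, forward, target = toy_setup
        shifted = ExperimentRecord(target.t, target.displacement,
                                   target.nominal_stress + 10.0)
        assert objective_rmse(base, spec, [shifted], forward) == \
            pytest.approx(10.0, rel=1e-12)

    def test_perturbed_parameter_increases_rmse(self, toy_setup):
        spec, base, forward, target = toy_setup
        worse = base.replace(mu_inf=base.mu_inf * 1.5)
        assert objective_rmse(worse, spec, [target], forward) > \
            objective_rmse(base, spec, [target], forward)


class TestFit:
    def test_single_parameter_recovery(self, toy_setup):
        spec, base, forward, target = toy_setup
        res = fit_parameters(spec, [target], forward, seed=1)
        assert res.params.mu_inf == pytest.approx(base.mu_inf, rel=1e-6)
        assert res.rmse < 1e-8
        assert res.status > 0

    def test_bound_is_hit_when_truth_sits_on_it(self, toy_setup):
        spec, base, forward, target = toy_setup
        # truth mu_inf = -50; restrict the search above it
        spec.bounds = {"mu_inf": (-40.0, -1.0)}
        res = fit_parameters(spec, [target], forward, seed=1)
        assert res.x[0] == pytest.approx(-40.0, rel=1e-9)

    def test_deterministic_given_seed(self, toy_setup):
        spec, base, forward, target = toy_setup
        r1 = fit_parameters(spec, [target], forward, seed=7)
        r2 = fit_parameters(spec, [target], forward, seed=7)
        assert np.allclose(r1.x, r2.x)

    def test_fitspec_validation(self):
        base = MaterialParameters(mu_inf=-50.0, alpha_inf=-5.0)
        with pytest.raises(ValueError):
            FitSpec(free=(), base=base, protocols=())
        with pytest.raises(ValueError):
            FitSpec(free=("not_a_parameter",), base=base, protocols=())
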