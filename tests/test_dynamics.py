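"""Reservoir and integrator dynamics against independent recurrence oracles."""

import numpy as np
import pytest
from scipy.stats import kstest

from reservoir_events.dynamics import (
    IntegratorParams,
    ReservoirParams,
    init_reservoir,
    run_linear_integrator,
    run_reservoir,
    step_response,
    time_to_stabilize,
)


def brute_force_reservoir(W, Win, alpha, U, x0):
    """Literal step-by-step evaluation of the state update, kept separate
    from the implementation on purpose."""
    x = np.array(x0, dtype=float)
    out = []
    for u in U:
        x = (1 - alpha) * x + alpha * np.tanh(W.dot(x) + Win.dot(u))
        out.append(x.copy())
    return np.array(out)


class TestInitReservoir:
    def test_defaults_match_standard_configuration(self):
        p = init_reservoir(N=10, K=4, seed=0)
        assert p.alpha == 0.05 and p.weight_range == (-0.5, 0.5)

    def test_deterministic_given_seed(self):
        a = init_reservoir(N=2, K=1, seed=42)
        b = init_reservoir(N=2, K=1, seed=42)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.Win, b.Win)

    def test_input_weights_uniform_by_ks(self):
        # Win is left unscaled: its 10^6 entries should pass a KS test
        # against Uniform(-0.5, 0.5)
        p = init_reservoir(N=1000, K=1000, alpha=0.1, seed=1)
        stat = kstest(p.Win.ravel(), "uniform", args=(-0.5, 1.0))
        assert stat.pvalue > 0.01

    def test_recurrent_weights_uniform_after_rescaling(self):
        # W is uniform up to the spectral-radius rescaling factor
        p = init_reservoir(N=500, K=2, seed=3)
        w = p.W.ravel()
        half = np.abs(w).max()
        stat = kstest(w, "uniform", args=(-half, 2 * half))
        assert stat.pvalue > 0.01

    def test_spectral_radius_rescaled_to_one(self):
        p = init_reservoir(N=80, K=3, seed=5)
        assert np.isclose(p.measured_spectral_radius(), 1.0)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            init_reservoir(N=4, K=2, alpha=0.0, seed=0)
        with pytest.raises(ValueError, match="alpha"):
            init_reservoir(N=4, K=2, alpha=1.5, seed=0)


class TestRunReservoir:
    def test_zero_input_zero_state_fixed_point(self, small_reservoir):
        traj = run_reservoir(small_reservoir, np.zeros((10, 20)))
        assert np.array_equal(traj.states, np.zeros((10, 120)))

    def test_memoryless_limit(self):
        # alpha=1, W=0, Win=I: state jumps to tanh(c) from the first step
        p = ReservoirParams(N=3, K=3, W=np.zeros((3, 3)), Win=np.eye(3),
                            alpha=1.0, seed=0)
        c = np.array([0.3, -0.7, 1.2])
        traj = run_reservoir(p, np.tile(c, (5, 1)))
        assert np.allclose(traj.states, np.tanh(c))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            N, K, T = rng.integers(1, 6), rng.integers(1, 4), rng.integers(1, 11)
            W = rng.uniform(-0.5, 0.5, (N, N))
            Win = rng.uniform(-0.5, 0.5, (N, K))
            alpha = float(rng.uniform(0.01, 1.0))
            U = rng.standard_normal((T, K))
            x0 = rng.uniform(-0.9, 0.9, N)
            p = ReservoirParams(N=int(N), K=int(K), W=W, Win=Win,
                                alpha=alpha, seed=0)
            traj = run_reservoir(p, U, x0)
            assert np.allclose(traj.states,
                               brute_force_reservoir(W, Win, alpha, U, x0),
                               atol=1e-12)

    def test_states_bounded(self, small_reservoir, rng):
        U = 5 * rng.standard_normal((200, 20))
        traj = run_reservoir(small_reservoir, U,
                             x0=rng.uniform(-0.99, 0.99, 120))
        assert np.all(np.abs(traj.states) < 1.0)

    def test_superposition_fails(self, small_reservoir, rng):
        # the reservoir is a genuinely non-linear integrator
        u1 = rng.standard_normal((20, 20))
        u2 = rng.standard_normal((20, 20))
        s = run_reservoir(small_reservoir, u1 + u2).states
        s_sum = (run_reservoir(small_reservoir, u1).states
                 + run_reservoir(small_reservoir, u2).states)
        assert not np.allclose(s, s_sum, atol=1e-6)

    def test_dimension_mismatch_rejected(self, small_reservoir):
        with pytest.raises(ValueError, match="dimension"):
            run_reservoir(small_reservoir, np.zeros((5, 3)))

    def test_nonfinite_input_rejected(self, small_reservoir):
        U = np.zeros((3, 20))
        U[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            run_reservoir(small_reservoir, U)


class TestLinearIntegrator:
    def test_zero_input_geometric_decay(self):
        p = IntegratorParams(alpha=0.1, D=4)
        v = np.array([1.0, -2.0, 0.5, 3.0])
        traj = run_linear_integrator(p, np.zeros((30, 4)), x0=v)
        n = np.arange(1, 31)[:, None]
        assert np.allclose(traj.states, (0.9 ** n) * v)

    def test_constant_input_fixed_point_as_printed(self):
        # LI* = (1-a) LI* + (1+a) -> LI* = (1+a)/a = 21 at a = 0.05
        p = IntegratorParams(alpha=0.05, D=1)
        traj = run_linear_integrator(p, np.ones((600, 1)))
        assert np.isclose(traj.states[-1, 0], 21.0, atol=1e-6)

    def test_convex_mode_fixed_point_is_input(self):
        p = IntegratorParams(alpha=0.05, D=1, input_gain_mode="convex")
        traj = run_linear_integrator(p, np.ones((600, 1)))
        assert np.isclose(traj.states[-1, 0], 1.0, atol=1e-6)

    def test_superposition_holds(self, integrator, rng):
        u1 = rng.standard_normal((25, 20))
        u2 = rng.standard_normal((25, 20))
        lhs = run_linear_integrator(integrator, 2 * u1 + 3 * u2).states
        rhs = (2 * run_linear_integrator(integrator, u1).states
               + 3 * run_linear_integrator(integrator, u2).states)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            IntegratorParams(alpha=1.0, D=2)


class TestStepResponse:
    def test_zero_hold_gives_flat_zero(self, small_reservoir):
        traj = step_response(small_reservoir, 10, 10, 10, hold_value=0.0)
        assert np.array_equal(traj.states, np.zeros((30, 120)))

    def test_default_protocol_lengths(self, integrator):
        traj = step_response(integrator, hold_value=1.0)
        assert traj.T == 1500
        # integrator response approaches the fixed point at rate (1 - a)
        fp = integrator.input_gain / integrator.alpha
        seg = traj.states[500:900, 0]
        resid = np.abs(seg - fp)
        ratios = resid[1:] / resid[:-1]
        assert np.allclose(ratios, 1 - integrator.alpha, atol=1e-8)

    def test_integrator_stabilization_closed_form(self, integrator):
        # time to halve distance to asymptote: ceil(log .5 / log(1-a)) = 14
        traj = step_response(integrator, 0, 400, 0, hold_value=1.0)
        res = time_to_stabilize(traj, 0, 400)
        expected = int(np.ceil(np.log(0.5) / np.log(1 - integrator.alpha)))
        assert expected == 14
        assert np.all(res.times[~res.undefined] == expected)

    def test_reservoir_times_are_diverse(self):
        p = init_reservoir(N=400, K=10, alpha=0.05, seed=2)
        traj = step_response(p, 100, 300, 0, hold_value=0.5)
        res = time_to_stabilize(traj, 100, 300)
        t = res.times[res.defined()]
        assert t.size > 300 and np.unique(t).size > 5

    def test_unit_already_at_asymptote_flagged(self):
        from reservoir_events.dynamics import Trajectory
        states = np.zeros((40, 2))
        states[:, 1] = np.linspace(1, 0, 40)
        res = time_to_stabilize(Trajectory(states, "integrator"), 0, 40)
        assert res.undefined[0] and not res.undefined[1]

    def test_small_window_rejected(self, integrator):
        traj = step_response(integrator, 0, 10, 0, hold_value=1.0)
        with pytest.raises(ValueError, match="window"):
            time_to_stabilize(traj, 0, 3)
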