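"""Backward-induction solver: kernels, thresholds, oracle equivalences."""

import json

import numpy as np
import pytest

from omcd.core import MCDParams, confidence, precision_growth
from omcd.processes import simulate_generic_batch
from omcd.solver import (
    StateGrid,
    ThresholdPolicy,
    TransitionKernel,
    apply_policy,
    build_grid,
    confidence_benefit,
    confidence_threshold,
    gaussian_step_matrix,
    max_value_benefit,
    solve_optimal_stopping,
    stationary_kernel,
)


def solve_for(params, n_points=257, benefit=None):
    grid = build_grid(params, n_points=n_points)
    kernel = stationary_kernel(grid, params.gamma, params.kappa)
    return solve_optimal_stopping(params, kernel, benefit)


class TestGrid:
    def test_default_span(self, ref_params):
        g = build_grid(ref_params)
        assert g.half_width == pytest.approx(6 * np.sqrt(8.0))
        assert g.n == 513

    def test_midpoint_is_prior_gap(self):
        p = MCDParams(mu0=(1.5, 0.5))
        g = build_grid(p, n_points=101 * 2 + 33)  # any odd >= 33
        assert g.points[g.n // 2] == pytest.approx(p.delta_mu0)

    def test_uniform_and_symmetric(self, ref_params):
        g = build_grid(ref_params, n_points=33)
        np.testing.assert_allclose(np.diff(g.points), g.spacing, rtol=1e-12)
        np.testing.assert_allclose(g.points + g.points[::-1], 0.0, atol=1e-12)

    def test_degenerate_when_no_mode_noise(self):
        g = build_grid(MCDParams(gamma=0.0))
        assert g.degenerate and g.n == 1

    def test_small_or_even_counts_rejected(self, ref_params):
        for n in (5, 32, 100):
            with pytest.raises(ValueError):
                build_grid(ref_params, n_points=n)


class TestKernel:
    def test_rows_sum_to_one(self, ref_params):
        g = build_grid(ref_params, n_points=257)
        P = stationary_kernel(g, ref_params.gamma, ref_params.kappa).matrices
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_interior_row_moments(self, ref_params):
        """Zero-mean increments with variance 2*gamma*kappa."""
        g = build_grid(ref_params, n_points=513)
        P = stationary_kernel(g, ref_params.gamma, ref_params.kappa).matrices
        x = g.points
        interior = slice(g.n // 4, 3 * g.n // 4)
        means = P[interior] @ x
        np.testing.assert_allclose(means, x[interior], atol=g.spacing / 2)
        var = P[interior] @ x**2 - means**2
        np.testing.assert_allclose(
            var, 2 * ref_params.gamma * ref_params.kappa, rtol=0.05
        )

    def test_sign_flip_symmetry(self, ref_params):
        g = build_grid(ref_params, n_points=65)
        P = stationary_kernel(g, ref_params.gamma, ref_params.kappa).matrices
        np.testing.assert_allclose(P, P[::-1, ::-1], atol=1e-12)

    def test_small_step_warns_but_stays_stochastic(self, ref_params):
        g = build_grid(ref_params, n_points=65)
        with pytest.warns(RuntimeWarning):
            k = stationary_kernel(g, 1e-4, ref_params.kappa)
        np.testing.assert_allclose(k.matrices.sum(axis=1), 1.0, atol=1e-10)

    def test_zero_step_is_identity(self, ref_params):
        g = build_grid(ref_params, n_points=33)
        np.testing.assert_array_equal(gaussian_step_matrix(g, 0.0), np.eye(33))


class TestSolve:
    def test_terminal_threshold_closed_form(self, ref_policy, ref_params):
        p = ref_params
        assert ref_policy.omega_star[-1] == p.R / 2 - p.alpha * (p.kappa * p.T) ** p.nu
        assert ref_policy.omega_P[-1] == 0.5

    def test_bellman_consistency(self, ref_policy):
        Q, S = ref_policy.value_function, ref_policy.stop_value
        assert np.all(Q >= S - 1e-12)
        np.testing.assert_array_equal(Q[-1], S[-1])

    def test_value_symmetry_under_sign_flip(self, ref_policy):
        Q = ref_policy.value_function
        np.testing.assert_allclose(Q, Q[:, ::-1], atol=1e-9)

    def test_threshold_upper_interval_structure(self, rng):
        """Stop sets are upper intervals in |dmu|: no multiple crossings."""
        for _ in range(50):
            p = MCDParams(
                alpha=float(np.exp(rng.uniform(np.log(0.05), np.log(1.0)))),
                beta=float(rng.uniform(0.5, 8)),
                gamma=float(rng.uniform(0.5, 8)),
                nu=float(rng.uniform(0.25, 2)),
                kappa=0.05,  # T = 20 keeps 50 solves fast
            )
            pol = solve_for(p, n_points=129)
            assert "multiple_crossings" not in pol.flags

    def test_policy_enumeration_oracle(self, rng):
        """DP value equals the best of all 1024 state-wise stop rules.

        Horizon 3, five states: every assignment of stop/continue to
        the 5 states at t in {1, 2} is evaluated exactly by forward
        matrix propagation (stopping is forced at t = 3).
        """
        x = np.linspace(-2, 2, 5)
        grid = StateGrid(points=x, center=0.0, half_width=2.0)
        p = MCDParams(kappa=1 / 3, alpha=0.3, nu=1.0)
        costs = np.array([p.alpha * (p.kappa * t) ** p.nu for t in range(4)])
        for _ in range(20):
            K = rng.random((3, 5, 5)) + 0.05
            K /= K.sum(axis=2, keepdims=True)
            kernel = TransitionKernel(grid=grid, matrices=K, stationary=False)
            btab = rng.normal(0, 1, size=(3, 5))  # benefit(x_j, t)

            def benefit(xq, t, btab=btab):
                return np.interp(np.asarray(xq), x, btab[t - 1])

            pol = solve_optimal_stopping(p, kernel, benefit)
            S = btab - costs[1:, None]
            K2, K3 = K[1], K[2]
            best = np.full(5, -np.inf)
            for m1 in range(32):
                a1 = np.array([(m1 >> i) & 1 for i in range(5)], bool)
                for m2 in range(32):
                    a2 = np.array([(m2 >> i) & 1 for i in range(5)], bool)
                    v2 = np.where(a2, S[1], K3 @ S[2])
                    v1 = np.where(a1, S[0], K2 @ v2)
                    best = np.maximum(best, v1)
            np.testing.assert_allclose(pol.value_function[0], best, atol=1e-10)

    def test_deterministic_state_matches_prospective(self, rng):
        """gamma = 0: the online stop time is the prospective optimum
        (settings with an interior optimum z_hat >= kappa)."""
        from omcd.core import prospective_optimum

        checked = 0
        while checked < 20:
            p = MCDParams(
                alpha=float(np.exp(rng.uniform(np.log(0.05), np.log(0.5)))),
                nu=float(rng.uniform(0.5, 2)),
                beta=float(rng.uniform(0.5, 8)),
                gamma=0.0,
                mu0=(float(rng.uniform(0.2, 2.0)), 0.0),
            )
            z_hat, _ = prospective_optimum(p)
            if z_hat < p.kappa:
                continue
            pol = solve_for(p)
            b = simulate_generic_batch(p, 1, checked)
            stop = int(pol.stop_times(b.confidence_matrix(), b.delta_mu)[0])
            assert stop == int(round(z_hat / p.kappa))
            checked += 1

    def test_grid_convergence(self, ref_params):
        """Doubling the grid moves the confidence threshold < 1e-3."""
        a = solve_for(ref_params, n_points=513).omega_P
        b = solve_for(ref_params, n_points=1025).omega_P
        assert np.max(np.abs(a - b)) < 1e-3


class TestConfidenceThreshold:
    def test_identity_and_terminal(self, ref_policy, ref_params):
        wp = confidence_threshold(ref_policy, ref_params)
        np.testing.assert_allclose(wp, ref_policy.omega_P, atol=1e-12)
        assert wp[-1] == pytest.approx(0.5, abs=1e-12)
        assert np.all(ref_policy.omega_P >= 0.5) and np.all(ref_policy.omega_P < 1)

    def test_zero_cost_identity(self):
        p = MCDParams(alpha=0.0)
        pol = solve_for(p)
        np.testing.assert_allclose(pol.omega_P, pol.omega_star / p.R, atol=1e-12)

    def test_rejects_non_confidence_policy(self, ref_params):
        pol = solve_for(ref_params, benefit=max_value_benefit(ref_params))
        with pytest.raises(ValueError):
            confidence_threshold(pol, ref_params)

    def test_rule_equivalence_on_trajectories(self, ref_policy, ref_params):
        """Net-benefit and confidence stopping rules agree trajectory-wise."""
        p = ref_params
        batch = simulate_generic_batch(p, 100, 123)
        conf = batch.confidence_matrix()
        t = np.arange(1, p.T + 1)
        costs = np.asarray(p.cost(t))
        nb = p.R * conf[:, 1:] - costs[None, :]
        cross_nb = nb >= ref_policy.omega_star[None, :]
        cross_pc = conf[:, 1:] >= ref_policy.omega_P[None, :]

        def first_stop(c):
            hit = c.any(axis=1)
            return np.where(hit, np.argmax(c, axis=1) + 1, p.T)

        np.testing.assert_array_equal(first_stop(cross_nb), first_stop(cross_pc))


class TestMaxValueBenefit:
    def test_no_preference_gives_mean_option_value(self):
        p = MCDParams(mu0=(2.0, 1.0))
        b = max_value_benefit(p)
        assert b(0.0, 1) == pytest.approx(p.R * 1.5)

    def test_gap_adds_half_absolute_difference(self):
        p = MCDParams()
        b = max_value_benefit(p)
        for x in (0.5, -0.5, 2.0):
            assert b(x, 3) - b(0.0, 3) == pytest.approx(p.R * abs(x) / 2)

    def test_insensitive_to_precision_efficacy(self, ref_params):
        """Unlike the confidence rule, thresholds ignore beta entirely."""
        pols = [
            solve_for(ref_params.replace(beta=b), benefit=max_value_benefit(ref_params))
            for b in (0.5, 4.0)
        ]
        np.testing.assert_array_equal(pols[0].omega_star, pols[1].omega_star)
        np.testing.assert_array_equal(pols[0].delta_mu_star, pols[1].delta_mu_star)


class TestThresholdShapes:
    """Qualitative effects of the decision parameters on the thresholds."""

    @staticmethod
    def omega_P(**kw):
        base = dict(R=1, alpha=1, nu=1, beta=1, gamma=1, kappa=0.01)
        return solve_for(MCDParams(**{**base, **kw})).omega_P

    def test_efficacy_raises_demand_for_confidence(self):
        base = self.omega_P()
        assert np.all(self.omega_P(beta=3) >= base - 1e-12)
        assert np.all(self.omega_P(gamma=3) >= base - 1e-12)

    def test_effort_cost_lowers_demand(self):
        assert np.all(self.omega_P(alpha=2) <= self.omega_P() + 1e-12)

    def test_cost_power_shapes_profile(self):
        late = self.omega_P(nu=2)
        assert np.all(np.diff(late[40:95]) <= 1e-12)  # superlinear: decaying
        early = self.omega_P(nu=0.5)
        assert np.all(np.diff(early[:25]) >= -1e-12)  # sublinear: rising


class TestApplyPolicy:
    def test_immediate_and_forced_stops(self, ref_policy, ref_params):
        T = ref_params.T

        class Traj:
            def __init__(self, conf, dmu):
                self._c, self.delta_mu = conf, dmu

            def confidence_series(self):
                return self._c

        high = Traj(np.full(T + 1, 0.999), np.full(T + 1, 5.0))
        assert apply_policy(high, ref_policy, ref_params) == 1
        flat = Traj(np.full(T + 1, 0.5), np.zeros(T + 1))
        assert apply_policy(flat, ref_policy, ref_params) == T

    def test_exact_threshold_equality_stops(self, ref_policy, ref_params):
        T = ref_params.T
        conf = np.full(T + 1, 0.5)
        t_hit = 40
        conf[t_hit] = ref_policy.omega_P[t_hit - 1]  # exact tie

        class Traj:
            delta_mu = np.zeros(T + 1)

            def confidence_series(self):
                return conf

        assert apply_policy(Traj(), ref_policy, ref_params) == t_hit

    def test_short_trajectory_rejected(self, ref_policy, ref_params):
        class Traj:
            delta_mu = np.zeros(10)

            def confidence_series(self):
                return np.full(10, 0.6)

        with pytest.raises(ValueError):
            apply_policy(Traj(), ref_policy, ref_params)


class TestSerialization:
    def test_json_round_trip_bit_exact(self, ref_policy):
        text = ref_policy.to_json()
        back = ThresholdPolicy.from_json(text)
        np.testing.assert_array_equal(back.omega_star, ref_policy.omega_star)
        np.testing.assert_array_equal(back.omega_P, ref_policy.omega_P)
        np.testing.assert_array_equal(back.delta_mu_star, ref_policy.delta_mu_star)
        np.testing.assert_array_equal(back.grid.points, ref_policy.grid.points)
        assert back.params == ref_policy.params
        assert back.to_json() == text
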