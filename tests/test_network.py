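"""Canonical network: dynamics, cost, plasticity, gradient consistency."""

import numpy as np
import pytest

from neurofep._utils import logit, sigmoid
from neurofep.generative import ExperimentDesign, generate_experiment
from neurofep.network import (
    cost_function,
    integrate_dynamics,
    net_threshold,
    plasticity_gradient,
    response_fixed_point,
    simulate_network_training,
    sufficient_stats,
    threshold_from_weights,
    weights_fixed_point,
)
from neurofep.synthetic import specificity_curve


def random_instance(rng, n_inputs=32):
    W1 = rng.normal(0, 1, (2, n_inputs))
    W0 = rng.normal(0, 1, (2, n_inputs))
    phi1 = rng.normal(-0.7, 0.3, 2)
    phi0 = rng.normal(-0.7, 0.3, 2)
    o = (rng.random((5, n_inputs)) < 0.5).astype(float)
    return W1, W0, phi1, phi0, o


def numerical_gradient(f, x, h=1e-6):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += h
        xm = x.copy()
        xm[idx] -= h
        g[idx] = (f(xp) - f(xm)) / (2 * h)
    return g


class TestThresholds:
    def test_zero_weights_give_uniform_log_term(self):
        W = np.zeros((2, 32))
        h1, h0 = threshold_from_weights(W, W, np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(h1, 32 * np.log(0.5))
        np.testing.assert_allclose(h0, 32 * np.log(0.5))

    def test_saturating_weights_drive_threshold_down(self):
        W = np.full((2, 32), 30.0)
        h1, _ = threshold_from_weights(W, np.zeros((2, 32)), np.zeros(2), np.zeros(2))
        assert np.all(h1 < -900)


class TestResponses:
    def test_zero_drive_gives_half(self):
        x = response_fixed_point(np.zeros(32), np.zeros((2, 32)), np.zeros(2))
        np.testing.assert_allclose(x, 0.5)

    def test_saturation(self):
        x = response_fixed_point(np.zeros(32), np.zeros((2, 32)), np.full(2, 30.0))
        assert np.all(np.abs(x - 1.0) < 1e-9)

    def test_fixed_point_self_consistency(self, rng):
        W1, W0, phi1, phi0, o = random_instance(rng)
        h = net_threshold(W1, W0, phi1, phi0)
        x = response_fixed_point(o[0], W1 - W0, h)
        residual = -logit(x) + (W1 - W0) @ o[0] + h
        assert np.abs(residual).max() < 1e-10

    def test_euler_integration_converges_to_fixed_point(self, rng):
        W1, W0, phi1, phi0, o = random_instance(rng, n_inputs=8)
        h = net_threshold(W1, W0, phi1, phi0)
        x_star = response_fixed_point(o[0], W1 - W0, h)
        x = integrate_dynamics(o[0], W1 - W0, h, np.array([0.3, 0.9]), n_steps=500)
        assert np.abs(x - x_star).max() < 1e-6
        # starting at the fixed point, stay there
        x2 = integrate_dynamics(o[0], W1 - W0, h, x_star, n_steps=50)
        np.testing.assert_allclose(x2, x_star, atol=1e-9)

    def test_cost_non_increasing_along_trajectory(self, rng):
        W1, W0, phi1, phi0, o = random_instance(rng, n_inputs=8)
        h = net_threshold(W1, W0, phi1, phi0)
        x = np.array([0.3, 0.9])
        costs = []
        for _ in range(200):
            costs.append(cost_function(x, o[0], W1, W0, phi1, phi0))
            x = integrate_dynamics(o[0], W1 - W0, h, x, n_steps=1)
        assert np.all(np.diff(costs) <= 1e-10)


class TestCostGradients:
    def test_gradient_wrt_responses_matches_dynamics(self, rng):
        """-dL/dx equals the right-hand side of the response dynamics."""
        W1, W0, phi1, phi0, o = random_instance(rng)
        h = net_threshold(W1, W0, phi1, phi0)
        x0 = rng.uniform(0.2, 0.8, (3, 2))
        num = numerical_gradient(
            lambda x: cost_function(x, o[:3], W1, W0, phi1, phi0), x0
        )
        analytic = logit(x0) - (o[:3] @ (W1 - W0).T + h)
        assert np.abs(num - analytic).max() < 1e-6

    def test_gradient_zero_at_response_fixed_point(self, rng):
        W1, W0, phi1, phi0, o = random_instance(rng)
        h = net_threshold(W1, W0, phi1, phi0)
        x = response_fixed_point(o[:3], W1 - W0, h)
        num = numerical_gradient(
            lambda xx: cost_function(xx, o[:3], W1, W0, phi1, phi0), x
        )
        assert np.abs(num).max() < 1e-5

    def test_plasticity_rule_is_weight_gradient(self, rng):
        """The Hebbian/homeostatic increments equal -(1/t) dL/dW."""
        W1, W0, phi1, phi0, _ = random_instance(rng, n_inputs=6)
        o = (rng.random((40, 6)) < 0.5).astype(float)
        x = rng.uniform(0.1, 0.9, (40, 2))
        stats = sufficient_stats(x, o)
        d1, d0 = plasticity_gradient(stats, W1, W0)
        t = 40
        num1 = numerical_gradient(
            lambda w: -cost_function(x, o, w, W0, phi1, phi0) / t, W1
        )
        num0 = numerical_gradient(
            lambda w: -cost_function(x, o, W1, w, phi1, phi0) / t, W0
        )
        assert np.abs(num1 - d1).max() < 1e-6
        assert np.abs(num0 - d0).max() < 1e-6

    def test_hand_evaluated_single_trial(self):
        """One trial, zero weights, balanced factors, x = 0.5: every term
        is computable in closed form."""
        W = np.zeros((2, 4))
        phi = np.log([0.5, 0.5])
        x = np.array([0.5, 0.5])
        o = np.array([1.0, 0.0, 1.0, 1.0])
        # entropy: 2 * 2 * 0.5 ln 0.5; evidence: 4 ln 0.5 per block row;
        # prior: ln 0.5 per row
        expected = 2 * (2 * 0.5 * np.log(0.5)) - 2 * (
            0.5 * (4 * np.log(0.5) + np.log(0.5)) * 2
        )
        got = cost_function(x, o, W, W, phi, phi)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_boundary_response_rejected(self):
        with pytest.raises(ValueError):
            cost_function(
                np.array([0.0, 0.5]), np.ones(4), np.zeros((2, 4)),
                np.zeros((2, 4)), np.zeros(2), np.zeros(2),
            )


class TestWeightFixedPoint:
    def test_zero_increment_at_fixed_point(self, rng):
        o = (rng.random((200, 6)) < 0.5).astype(float)
        x = rng.uniform(0.2, 0.8, (200, 2))
        stats = sufficient_stats(x, o)
        W1, W0 = weights_fixed_point(stats)
        d1, d0 = plasticity_gradient(stats, W1, W0)
        assert np.abs(d1).max() < 1e-12
        assert np.abs(d0).max() < 1e-12

    def test_deterministic_coupling_hits_clip(self):
        o = np.tile(np.array([1.0, 0.0]), (50, 3))[:, :6]
        x = np.tile(o[:, :1], (1, 2))  # x identical to input 1
        W1, _ = weights_fixed_point(sufficient_stats(x, o))
        np.testing.assert_allclose(W1[:, 0], logit(np.array(1 - 1e-3)))

    def test_independent_response_gives_zero_weight(self, rng):
        o = (rng.random((20000, 4)) < 0.5).astype(float)
        x = np.full((20000, 2), 0.5)
        x += rng.normal(0, 1e-3, x.shape)  # break exact degeneracy
        W1, W0 = weights_fixed_point(sufficient_stats(x, o))
        assert np.abs(sigmoid(W1) - 0.5).max() < 0.02
        assert np.abs(sigmoid(W0) - 0.5).max() < 0.02

    def test_recovery_of_generating_network(self, rng):
        """Responses produced by a known network re-estimate its weights."""
        W1 = logit(rng.uniform(0.3, 0.7, (2, 8)))
        W0 = logit(rng.uniform(0.3, 0.7, (2, 8)))
        phi = np.log([0.5, 0.5])
        o = (rng.random((25600, 8)) < 0.5).astype(float)
        h = net_threshold(W1, W0, phi, phi)
        x = response_fixed_point(o, W1 - W0, h)
        W1_hat, W0_hat = weights_fixed_point(sufficient_stats(x, o))
        # the estimator recovers the self-consistent parameterisation of
        # the response distribution: responses regenerated from the
        # estimate match the originals
        x_hat = response_fixed_point(
            o, W1_hat - W0_hat, net_threshold(W1_hat, W0_hat, phi, phi)
        )
        assert np.abs(x - x_hat).mean() < 0.05


class TestTraining:
    def test_specificity_emerges_under_balanced_factors(self):
        design = ExperimentDesign(seed=3)
        sources, stimuli, _ = generate_experiment(design)
        sim = simulate_network_training(
            stimuli, np.log([0.5, 0.5]), np.log([0.5, 0.5]), rng=7
        )
        spec1 = specificity_curve(sim.x, sources, ensemble=0, source=0)
        spec2 = specificity_curve(sim.x, sources, ensemble=1, source=1)
        assert spec1[-1] > 0.3 and spec2[-1] > 0.3
        assert spec1[4] < spec1[-1]  # learning is gradual

    def test_biased_factors_disrupt_learning(self):
        design = ExperimentDesign(seed=3)
        sources, stimuli, _ = generate_experiment(design)
        runs = {}
        for p in (0.5, 0.8, 0.2):
            sim = simulate_network_training(
                stimuli, np.log([p, p]), np.log([1 - p, 1 - p]), rng=7
            )
            runs[p] = specificity_curve(sim.x, sources, ensemble=0)[-1]
        assert runs[0.5] > runs[0.8]
        assert runs[0.5] > runs[0.2]

    def test_session_cost_non_increasing_under_repeated_stimuli(self):
        design = ExperimentDesign(seed=4)
        _, stimuli, _ = generate_experiment(design)
        sim = simulate_network_training(
            stimuli, np.log([0.5, 0.5]), np.log([0.5, 0.5]), rng=9
        )
        tol = 1e-6 * np.abs(sim.cost_sessions).mean()
        assert np.all(np.diff(sim.cost_sessions) <= tol)

    def test_reduced_plasticity_slows_weight_drift(self):
        design = ExperimentDesign(n_sessions=30, seed=5)
        _, stimuli, _ = generate_experiment(design)
        full = simulate_network_training(
            stimuli, np.log([0.5, 0.5]), np.log([0.5, 0.5]), rng=2
        )
        slow = simulate_network_training(
            stimuli, np.log([0.5, 0.5]), np.log([0.5, 0.5]),
            plasticity_rate=0.01, rng=2,
        )

        def drift(sim):
            return np.abs(np.diff(sigmoid(sim.W1_sessions), axis=0)).sum()

        assert 0.0 < drift(slow) < drift(full)
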