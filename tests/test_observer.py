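"""Ideal observer: belief updates, free energy, parameter recovery."""

import itertools

import numpy as np
import pytest
from scipy.special import digamma

from neurofep.generative import ExperimentDesign, StatePrior, generate_experiment
from neurofep.observer import (
    dirichlet_update,
    expected_log_likelihood,
    free_energy,
    joint_evidence,
    posterior_mean_A,
    run_ideal_observer,
    state_posterior_update,
)


def exact_joint_posterior(o, ln_A, ln_D):
    """Brute-force Bayes over the four joint source states."""
    logp = np.empty((2, 2))
    for k, l in itertools.product((0, 1), repeat=2):
        logp[k, l] = (
            ln_D[0][k]
            + ln_D[1][l]
            + float(o @ ln_A[:, 1, k, l] + (1 - o) @ ln_A[:, 0, k, l])
        )
    p = np.exp(logp - logp.max())
    return p / p.sum()


def random_factorised_tensor(rng, n_inputs=8):
    """Additive (per-source) expected log likelihood tensor."""
    p1 = rng.uniform(0.2, 0.8, (n_inputs, 2))  # P(o=1 | s1 = v)
    p2 = rng.uniform(0.2, 0.8, (n_inputs, 2))
    ln_A = np.empty((n_inputs, 2, 2, 2))
    for k, l in itertools.product((0, 1), repeat=2):
        ln_A[:, 1, k, l] = np.log(p1[:, k]) + np.log(p2[:, l])
        ln_A[:, 0, k, l] = np.log1p(-p1[:, k]) + np.log1p(-p2[:, l])
    return ln_A


class TestStatePosterior:
    def test_uniform_evidence_and_prior_gives_half(self):
        ln_A = np.full((8, 2, 2, 2), np.log(0.5))
        q = state_posterior_update(np.ones(8), ln_A, StatePrior().log())
        np.testing.assert_allclose(q, 0.5)

    def test_prior_only_inference_returns_prior(self):
        ln_A = np.full((8, 2, 2, 2), np.log(0.5))
        q = state_posterior_update(
            np.zeros(8), ln_A, StatePrior((0.8, 0.3)).log()
        )
        np.testing.assert_allclose(q[0], [0.2, 0.8], atol=1e-12)
        np.testing.assert_allclose(q[1], [0.7, 0.3], atol=1e-12)

    def test_matches_exact_bayes_when_joint_factorises(self, rng):
        """For an additive tensor the exact joint posterior is a product
        and mean field must reproduce its marginals exactly."""
        ln_A = random_factorised_tensor(rng)
        ln_D = StatePrior((0.6, 0.4)).log()
        for _ in range(20):
            o = (rng.random(8) < 0.5).astype(float)
            joint = exact_joint_posterior(o, ln_A, ln_D)
            q = state_posterior_update(o, ln_A, ln_D)
            np.testing.assert_allclose(q[0], joint.sum(axis=1), atol=1e-9)
            np.testing.assert_allclose(q[1], joint.sum(axis=0), atol=1e-9)

    def test_variational_bound_on_true_likelihood(self, rng):
        """Mean-field free energy never beats the exact log evidence."""
        from neurofep.generative import build_mixing_matrix

        A = build_mixing_matrix(0.25, 8)
        ln_A = np.log(np.clip(A.entries, 1e-12, 1.0))
        ln_D = StatePrior().log()
        for _ in range(20):
            o = (rng.random(8) < 0.5).astype(float)
            q = state_posterior_update(o, ln_A, ln_D)
            E = joint_evidence(o, ln_A)
            logz = np.log(
                sum(
                    np.exp(E[k, l] + ln_D[0][k] + ln_D[1][l])
                    for k in (0, 1)
                    for l in (0, 1)
                )
            )
            f = free_energy(q[None], o[None], ln_A, ln_D)
            assert f >= -logz - 1e-9

    def test_posterior_constant_under_repeated_observation(self):
        ln_A = np.log(np.clip(np.random.default_rng(0).uniform(0.1, 0.9, (8, 2, 2, 2)), 0, 1))
        ln_D = StatePrior().log()
        o = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        q1 = state_posterior_update(o, ln_A, ln_D)
        q2 = state_posterior_update(o, ln_A, ln_D)
        np.testing.assert_array_equal(q1, q2)


class TestDirichlet:
    def test_delta_posterior_increments_single_slice(self):
        a = np.ones((4, 2, 2, 2))
        q = np.array([[0.0, 1.0], [0.0, 1.0]])  # both sources ON
        a2 = dirichlet_update(a, np.ones(4), q)
        assert np.allclose(a2[:, 1, 1, 1], 2.0)
        mask = np.ones_like(a, bool)
        mask[:, 1, 1, 1] = False
        assert np.allclose(a2[mask], a[mask])

    def test_uniform_posterior_splits_mass(self):
        a = np.ones((4, 2, 2, 2))
        q = np.full((2, 2), 0.5)
        o = np.array([1, 1, 0, 0], dtype=float)
        a2 = dirichlet_update(a, o, q)
        assert np.allclose(a2[:2, 1] - 1.0, 0.25)
        assert np.allclose(a2[2:, 0] - 1.0, 0.25)

    def test_mass_conservation_over_trials(self, rng):
        a = np.ones((6, 2, 2, 2))
        T = 37
        for _ in range(T):
            o = (rng.random(6) < 0.5).astype(float)
            p = rng.random(2)
            q = np.stack([[1 - p[0], p[0]], [1 - p[1], p[1]]])
            a = dirichlet_update(a, o, q)
        np.testing.assert_allclose(a.sum(axis=(1, 2, 3)), 8.0 + T)


class TestExpectedLogLikelihood:
    def test_symmetric_pair(self):
        a = np.full((1, 2, 1, 1), 3.5)
        ln_A = expected_log_likelihood(a)
        expected = digamma(3.5) - digamma(7.0)
        np.testing.assert_allclose(ln_A, expected)

    def test_large_counts_approach_log_proportion(self):
        a = np.zeros((1, 2, 1, 1))
        a[0, 1] = 750.0
        a[0, 0] = 250.0
        ln_A = expected_log_likelihood(a)
        assert abs(ln_A[0, 1, 0, 0] - np.log(0.75)) < 0.01

    def test_unit_counts_give_exactly_minus_one(self):
        ln_A = expected_log_likelihood(np.ones((1, 2, 1, 1)))
        np.testing.assert_allclose(ln_A, -1.0)  # psi(1) - psi(2) = -1

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            expected_log_likelihood(np.zeros((1, 2, 1, 1)))

    def test_jensen_gap(self, rng):
        a = rng.uniform(0.5, 5.0, (4, 2, 2, 2))
        ln_A = expected_log_likelihood(a)
        assert np.all(np.exp(ln_A).sum(axis=1) < 1.0)


class TestFreeEnergy:
    def test_constant_evidence_posterior_at_prior(self):
        """With flat ln A = c everywhere and q at the prior the KL part
        vanishes and F = -T * n_inputs * c."""
        c = np.log(0.4)
        ln_A = np.full((8, 2, 2, 2), c)
        prior = StatePrior((0.7, 0.3))
        ln_D = prior.log()
        q = np.stack([[0.3, 0.7], [0.7, 0.3]])
        T = 5
        o = (np.arange(T * 8).reshape(T, 8) % 3 == 0).astype(float)
        f = free_energy(np.tile(q, (T, 1, 1)), o, ln_A, ln_D)
        np.testing.assert_allclose(f, -T * 8 * c, atol=1e-9)

    def test_delta_posterior_under_deterministic_mixing(self):
        """Accuracy term vanishes when the delta posterior matches the
        truth and the mixing is deterministic: F is the prior log-score."""
        from neurofep.generative import build_mixing_matrix

        A = build_mixing_matrix(0.0, 8)
        ln_A = np.log(np.clip(A.entries, 1e-300, 1.0))
        prior = StatePrior((0.6, 0.6))
        s = (1, 0)
        o = A.entries[:, 1, s[0], s[1]]  # deterministic observation
        q = np.zeros((2, 2))
        q[0, s[0]] = 1.0
        q[1, s[1]] = 1.0
        f = free_energy(q[None], o[None], ln_A, prior.log())
        np.testing.assert_allclose(f, -(np.log(0.6) + np.log(0.4)), atol=1e-9)

    def test_additive_over_trials(self, rng):
        ln_A = np.log(rng.uniform(0.1, 0.9, (8, 2, 2, 2)))
        ln_D = StatePrior().log()
        o = (rng.random((6, 8)) < 0.5).astype(float)
        q = rng.random((6, 2, 1))
        q = np.concatenate([1 - q, q], axis=2)
        total = free_energy(q, o, ln_A, ln_D)
        parts = sum(free_energy(q[t][None], o[t][None], ln_A, ln_D) for t in range(6))
        np.testing.assert_allclose(total, parts, rtol=1e-12)


class TestIdealObserver:
    def test_parameter_recovery_at_standard_mixing(self):
        """After 25600 fresh trials the posterior mean of every likelihood
        cell lies within 0.05 of the generating tensor."""
        design = ExperimentDesign(seed=1, repeat_identical_sequence=False)
        _, stimuli, A = generate_experiment(design)
        traj = run_ideal_observer(
            stimuli, StatePrior(), schedule="per_session", record_free_energy=False
        )
        A_hat = posterior_mean_A(traj.a_final)
        assert np.abs(A_hat - A.entries).max() < 0.05
        # the mixed element converges to the designed 75%
        assert abs(A_hat[:16, 1, 1, 0].mean() - 0.75) < 0.03

    def test_posteriors_normalised_and_mass_conserved(self):
        design = ExperimentDesign(n_sessions=2, seed=3)
        _, stimuli, _ = generate_experiment(design)
        traj = run_ideal_observer(stimuli, StatePrior(), record_free_energy=False)
        np.testing.assert_allclose(traj.posteriors.sum(axis=2), 1.0, atol=1e-9)
        added = traj.a_final.sum(axis=(1, 2, 3)) - 8.0 - 2 * 0.1 * 2
        np.testing.assert_allclose(added, stimuli.shape[0], atol=1e-6)

    def test_inseparable_mixing_leaves_specificity_flat(self):
        from neurofep.synthetic import specificity_curve

        design = ExperimentDesign(n_sessions=20, mix_fraction=0.5, seed=5)
        sources, stimuli, _ = generate_experiment(design)
        traj = run_ideal_observer(
            stimuli, StatePrior(), schedule="per_session", record_free_energy=False
        )
        spec = specificity_curve(traj.p_on, sources, ensemble=0)
        assert abs(spec[-1]) < 0.1

    def test_schedules_agree_on_learned_parameters(self):
        design = ExperimentDesign(n_sessions=10, seed=6, repeat_identical_sequence=False)
        _, stimuli, _ = generate_experiment(design)
        t_on = run_ideal_observer(stimuli, StatePrior(), record_free_energy=False)
        t_ps = run_ideal_observer(
            stimuli, StatePrior(), schedule="per_session", record_free_energy=False
        )
        a_on = posterior_mean_A(t_on.a_final)
        a_ps = posterior_mean_A(t_ps.a_final)
        assert np.abs(a_on - a_ps).max() < 0.1
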