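"""Ideal variational Bayesian observer for the two-source mixing model.

Mean-field categorical/Dirichlet belief updating.  The posterior over the
two sources factorises, ``Q(s) = Q(s1) Q(s2)``, and the posterior over the
likelihood tensor is Dirichlet over the ON/OFF axis of each
(input, s1, s2) cell.  Per trial the observer:

1. forms the expected log likelihood ``ln A = psi(a) - psi(a_1 + a_0)``
   (digamma difference over the observation axis),
2. infers the state posterior as a per-source softmax of the summed
   evidence plus the log prior (a coupled mean-field fixed point, iterated
   to convergence), and
3. accrues Dirichlet counts by the outer product of the observation with
   the joint state posterior, so each trial adds unit mass per input.

Variational free energy is accumulated as the time sum of
``s . (ln s - ln A . o - ln D)``; the parameter-complexity term, constant
in the states, is omitted throughout (it cancels in all comparisons made
here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

from ._utils import xlogx
from .generative import StatePrior

__all__ = [
    "ObserverTrajectory",
    "expected_log_likelihood",
    "state_posterior_update",
    "dirichlet_update",
    "joint_evidence",
    "free_energy",
    "posterior_mean_A",
    "run_ideal_observer",
    "write_observer_trajectory_csv",
    "write_dirichlet_snapshots_json",
]


def expected_log_likelihood(a: np.ndarray) -> np.ndarray:
    """E_Q[ln A] = psi(a) - psi(a_1 + a_0), elementwise over the tensor.

    ``a`` has shape (n_inputs, 2, 2, 2) with axis 1 the observation value;
    all concentrations must be strictly positive.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0.0):
        raise ValueError("Dirichlet concentrations must be > 0")
    return digamma(a) - digamma(a.sum(axis=1, keepdims=True))


def posterior_mean_A(a: np.ndarray) -> np.ndarray:
    """Posterior expectation of A: concentrations normalised over the
    observation axis."""
    a = np.asarray(a, dtype=float)
    return a / a.sum(axis=1, keepdims=True)


def joint_evidence(o: np.ndarray, ln_A: np.ndarray) -> np.ndarray:
    """Accumulated log evidence E[k, l] for each joint source state.

    E[k, l] = sum_i o_i ln A[i, 1, k, l] + (1 - o_i) ln A[i, 0, k, l];
    both observation levels contribute.
    """
    o = np.asarray(o, dtype=float)
    return np.einsum("i,ikl->kl", o, ln_A[:, 1]) + np.einsum(
        "i,ikl->kl", 1.0 - o, ln_A[:, 0]
    )


def state_posterior_update(
    o: np.ndarray,
    ln_A: np.ndarray,
    ln_D: np.ndarray,
    max_iter: int = 32,
    tol: float = 1e-10,
) -> np.ndarray:
    """Mean-field state posterior for one trial.

    Returns ``q`` of shape (2 sources, 2 values) with ``q[j, v] =
    Q(s_j = v)``.  Each source's marginal is the softmax of its log prior
    plus the evidence averaged under the other source's marginal; the two
    coupled updates are iterated to a fixed point.  The coupled updates can
    have several fixed points (the per-trial free energy is multimodal in
    the factorised posterior), so the iteration is restarted from the prior
    and from each corner of the state square, and the fixed point with the
    lowest free energy is returned; with evidence that is additive across
    sources all restarts coincide after one pass.
    """
    E = joint_evidence(o, ln_A)  # (2, 2) indexed [s1 value, s2 value]
    if not np.all(np.isfinite(E)):
        raise FloatingPointError("non-finite evidence in state posterior update")
    ln_D = np.asarray(ln_D, dtype=float)
    prior_q2 = _softmax(ln_D[1])
    eps = 1e-3
    starts = (
        prior_q2,
        np.array([1.0 - eps, eps]),
        np.array([eps, 1.0 - eps]),
    )
    best_q = None
    best_f = np.inf
    for q2 in starts:
        q1 = prior_q2  # overwritten on the first pass
        for _ in range(max_iter):
            q1 = _softmax(ln_D[0] + E @ q2)
            q2_new = _softmax(ln_D[1] + q1 @ E)
            delta = np.max(np.abs(q2_new - q2))
            q2 = q2_new
            if delta < tol:
                break
        f = (
            xlogx(q1).sum()
            + xlogx(q2).sum()
            - float(np.outer(q1, q2).ravel() @ E.ravel())
            - float(q1 @ ln_D[0])
            - float(q2 @ ln_D[1])
        )
        if f < best_f:
            best_f = f
            best_q = np.stack([q1, q2])
    return best_q


def _softmax(v: np.ndarray) -> np.ndarray:
    v = v - np.max(v)
    e = np.exp(v)
    return e / e.sum()


def _softmax_rows(m: np.ndarray) -> np.ndarray:
    return np.stack([_softmax(row) for row in m])


def _batch_state_posteriors(
    o_block: np.ndarray,
    ln_A: np.ndarray,
    ln_D: np.ndarray,
    max_iter: int = 32,
) -> np.ndarray:
    """Vectorised multi-start mean-field posteriors for a block of trials.

    Same computation as :func:`state_posterior_update` applied to each row
    of ``o_block`` under one fixed ``ln_A``; returns (T, 2, 2).
    """
    o_block = np.asarray(o_block, dtype=float)
    E = np.einsum("ti,ikl->tkl", o_block, ln_A[:, 1]) + np.einsum(
        "ti,ikl->tkl", 1.0 - o_block, ln_A[:, 0]
    )
    ln_D = np.asarray(ln_D, dtype=float)
    T = o_block.shape[0]
    eps = 1e-3
    prior_q2 = _softmax(ln_D[1])
    starts = (
        np.tile(prior_q2, (T, 1)),
        np.tile(np.array([1.0 - eps, eps]), (T, 1)),
        np.tile(np.array([eps, 1.0 - eps]), (T, 1)),
    )

    def softmax_rows(v):
        v = v - v.max(axis=1, keepdims=True)
        e = np.exp(v)
        return e / e.sum(axis=1, keepdims=True)

    best_f = np.full(T, np.inf)
    best_q1 = np.empty((T, 2))
    best_q2 = np.empty((T, 2))
    for q2 in starts:
        q2 = q2.copy()
        for _ in range(max_iter):
            q1 = softmax_rows(ln_D[0] + np.einsum("tkl,tl->tk", E, q2))
            q2_new = softmax_rows(ln_D[1] + np.einsum("tkl,tk->tl", E, q1))
            if np.max(np.abs(q2_new - q2)) < 1e-10:
                q2 = q2_new
                break
            q2 = q2_new
        f = (
            xlogx(q1).sum(axis=1)
            + xlogx(q2).sum(axis=1)
            - np.einsum("tkl,tk,tl->t", E, q1, q2)
            - q1 @ ln_D[0]
            - q2 @ ln_D[1]
        )
        better = f < best_f
        best_f = np.where(better, f, best_f)
        best_q1[better] = q1[better]
        best_q2[better] = q2[better]
    return np.stack([best_q1, best_q2], axis=1)


def dirichlet_update(a: np.ndarray, o: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Add one trial's outer product o (x) joint posterior to the counts.

    The joint posterior is the outer product of the per-source marginals
    (mean-field), so each input gains total mass 1 per trial.
    """
    a = np.asarray(a, dtype=float).copy()
    o = np.asarray(o, dtype=float)
    joint = np.outer(q[0], q[1])  # [s1 value, s2 value]
    a[:, 1] += o[:, None, None] * joint
    a[:, 0] += (1.0 - o)[:, None, None] * joint
    if np.any(a < 0):
        raise ValueError("negative Dirichlet concentration after update")
    return a


def free_energy(
    posteriors: np.ndarray,
    stimuli: np.ndarray,
    ln_A: np.ndarray,
    ln_D: np.ndarray,
) -> float:
    """Time-summed variational free energy (nats), complexity term omitted.

    ``posteriors`` is (T, 2, 2) of per-source marginals; the sum is
    additive over trials, and 0 ln 0 is treated as 0.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    stimuli = np.asarray(stimuli, dtype=float)
    E = np.einsum("ti,ikl->tkl", stimuli, ln_A[:, 1]) + np.einsum(
        "ti,ikl->tkl", 1.0 - stimuli, ln_A[:, 0]
    )
    q1, q2 = posteriors[:, 0], posteriors[:, 1]
    entropy = xlogx(posteriors).sum(axis=(1, 2))
    accuracy = np.einsum("tkl,tk,tl->t", E, q1, q2)
    prior_term = q1 @ np.asarray(ln_D, dtype=float)[0] + q2 @ np.asarray(ln_D)[1]
    return float((entropy - accuracy - prior_term).sum())


@dataclass
class ObserverTrajectory:
    """Per-trial posteriors plus per-session bookkeeping of one run."""

    posteriors: np.ndarray          # (T, 2, 2) per-source marginals
    a_final: np.ndarray             # final Dirichlet counts
    a_sessions: list[np.ndarray] = field(default_factory=list)
    free_energy_sessions: np.ndarray | None = None

    @property
    def p_on(self) -> np.ndarray:
        """Posterior P(s_j = 1) per trial, shape (T, 2)."""
        return self.posteriors[:, :, 1]


def write_observer_trajectory_csv(
    path, traj: ObserverTrajectory, session_length: int = 256
) -> None:
    """CSV of per-trial posteriors: session, trial, s1/s2 posterior P(on)."""
    import pandas as pd

    n = traj.posteriors.shape[0]
    pd.DataFrame(
        {
            "session": np.arange(n) // session_length + 1,
            "trial": np.arange(n) % session_length + 1,
            "s1_posterior": traj.p_on[:, 0],
            "s2_posterior": traj.p_on[:, 1],
        }
    ).to_csv(path, index=False)


def write_dirichlet_snapshots_json(path, traj: ObserverTrajectory) -> None:
    """Per-session Dirichlet concentration tensors as nested JSON lists."""
    import json

    payload = {
        "shape": list(traj.a_sessions[0].shape) if traj.a_sessions else [],
        "sessions": [a.tolist() for a in traj.a_sessions],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def run_ideal_observer(
    stimuli: np.ndarray,
    prior: StatePrior,
    a_init: float | np.ndarray = 1.0,
    a_init_bias: float = 0.1,
    schedule: str = "online",
    session_length: int = 256,
    record_free_energy: bool = True,
) -> ObserverTrajectory:
    """Sequential inference and learning over a stimulus sequence.

    ``schedule`` chooses when the expected log likelihood is refreshed:
    ``"online"`` recomputes it after every trial (inference and learning as
    a coupled fixed point), ``"per_session"`` once per block of
    ``session_length`` trials (faster; adiabatic approximation).

    The Dirichlet prior defaults to a flat count of 1 per cell plus a small
    structured bias ``a_init_bias`` tying source 1 to the first input group
    and source 2 to the second.  An exactly flat prior is a symmetric fixed
    point of the coupled inference/learning updates (constant evidence
    keeps the posterior at the prior, which in turn keeps the counts
    symmetric), so a perturbation is needed for learning to start; the
    structured form additionally pins which posterior label tracks which
    source, mirroring how the network's ensembles are labelled by their
    eventual preference.
    """
    stimuli = np.asarray(stimuli)
    n_trials, n_inputs = stimuli.shape
    if schedule not in ("online", "per_session"):
        raise ValueError(f"unknown schedule {schedule!r}")
    if np.isscalar(a_init):
        a = np.full((n_inputs, 2, 2, 2), float(a_init))
        half = n_inputs // 2
        # ON counts when the aligned source is ON, OFF counts when it is OFF
        a[:half, 1, 1, :] += a_init_bias
        a[:half, 0, 0, :] += a_init_bias
        a[half:, 1, :, 1] += a_init_bias
        a[half:, 0, :, 0] += a_init_bias
    else:
        a = np.asarray(a_init, dtype=float).copy()
    ln_D = prior.log()
    posteriors = np.empty((n_trials, 2, 2))
    a_sessions: list[np.ndarray] = []
    fe_sessions: list[float] = []
    ln_A = expected_log_likelihood(a)
    if schedule == "online":
        session_start = 0
        for t in range(n_trials):
            ln_A = expected_log_likelihood(a)
            q = state_posterior_update(stimuli[t], ln_A, ln_D)
            posteriors[t] = q
            a = dirichlet_update(a, stimuli[t], q)
            if (t + 1) % session_length == 0 or t == n_trials - 1:
                a_sessions.append(a.copy())
                if record_free_energy:
                    fe_sessions.append(
                        free_energy(
                            posteriors[session_start : t + 1],
                            stimuli[session_start : t + 1],
                            ln_A,
                            ln_D,
                        )
                    )
                session_start = t + 1
    else:  # per_session: whole blocks under one frozen ln_A (vectorised)
        for lo in range(0, n_trials, session_length):
            hi = min(lo + session_length, n_trials)
            block = stimuli[lo:hi].astype(float)
            q = _batch_state_posteriors(block, ln_A, ln_D)
            posteriors[lo:hi] = q
            a[:, 1] += np.einsum("ti,tk,tl->ikl", block, q[:, 0], q[:, 1])
            a[:, 0] += np.einsum("ti,tk,tl->ikl", 1.0 - block, q[:, 0], q[:, 1])
            if record_free_energy:
                fe_sessions.append(free_energy(q, block, ln_A, ln_D))
            ln_A = expected_log_likelihood(a)
            a_sessions.append(a.copy())
    return ObserverTrajectory(
        posteriors=posteriors,
        a_final=a,
        a_sessions=a_sessions,
        free_energy_sessions=np.asarray(fe_sessions) if record_free_energy else None,
    )
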