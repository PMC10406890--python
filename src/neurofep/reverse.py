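"""Reverse engineering of the implicit generative model from responses.

Given normalised ensemble response series x_t in (0,1)^2 and the stimuli
o_t, this module estimates

* threshold factors ``phi = ln(<x>; <1-x>)`` over an initial window, whose
  exponential is the implicit state prior D of the network;
* effective synaptic connectivity per session, as the weight fixed point
  applied to cumulative-from-start sufficient statistics;
* the posterior likelihood tensor encoded by the weights (A_1l = sig(W_l))
  and its normalised error against the ideal (Bayes-optimal) likelihood;
* empirical variational free energy per session, by substituting the
  observed responses into the network cost; and
* a two-coordinate free-energy landscape on which the per-session
  connectivity trajectory can be plotted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative import MixingMatrix, StatePrior
from .network import (
    SufficientStats,
    cost_function,
    net_threshold,
    response_fixed_point,
    sufficient_stats,
    weights_fixed_point,
)
from ._utils import logit, sigmoid

__all__ = [
    "ThresholdFactors",
    "FreeEnergyLandscape",
    "estimate_threshold_factors",
    "estimate_effective_connectivity",
    "connectivity_trajectory",
    "weights_to_posterior_A",
    "factorised_evidence_tensor",
    "ideal_marginal_A",
    "posterior_A_error",
    "empirical_free_energy",
    "landscape_projection",
    "write_reconstructed_model_json",
    "write_landscape_csv",
]


@dataclass(frozen=True)
class ThresholdFactors:
    """phi = (phi1; phi0) per ensemble; exp(phi1) is the implicit prior."""

    phi1: np.ndarray
    phi0: np.ndarray

    @property
    def d_hat(self) -> np.ndarray:
        """Implicit state prior expectation (P(s=1), P(s=0)) per ensemble."""
        return np.stack([np.exp(self.phi1), np.exp(self.phi0)], axis=1)


def estimate_threshold_factors(
    x: np.ndarray, n_init_sessions: int = 10, session_length: int = 256
) -> ThresholdFactors:
    """phi = ln of the temporal means of (x, 1-x) over the initial window.

    Because 1-x is one minus x by construction, exp(phi1) + exp(phi0) = 1
    exactly.  Raises on a degenerate (all-zero or all-one) ensemble.
    """
    if n_init_sessions < 1:
        raise ValueError("n_init_sessions must be >= 1")
    x = np.asarray(x, dtype=float)
    window = x[: n_init_sessions * session_length]
    mean_x = window.mean(axis=0)
    if np.any(mean_x <= 0.0) or np.any(mean_x >= 1.0):
        raise ValueError("degenerate ensemble: mean response at 0 or 1")
    return ThresholdFactors(phi1=np.log(mean_x), phi0=np.log(1.0 - mean_x))


def estimate_effective_connectivity(
    x: np.ndarray,
    o: np.ndarray,
    upto_session: int | None = None,
    session_length: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Effective (W1, W0) from cumulative statistics through a session.

    Uses all trials from the start through ``upto_session`` (1-based;
    default: all data), matching the from-the-start definition of the time
    average in the plasticity fixed point.
    """
    x = np.asarray(x, dtype=float)
    o = np.asarray(o, dtype=float)
    n = x.shape[0] if upto_session is None else upto_session * session_length
    if n < 1 or n > x.shape[0]:
        raise ValueError("upto_session outside the recorded range")
    return weights_fixed_point(sufficient_stats(x[:n], o[:n]))


def connectivity_trajectory(
    x: np.ndarray, o: np.ndarray, session_length: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Per-session (W1, W0) estimates, cumulative from session 1.

    Returns arrays of shape (n_sessions, 2, n_inputs).
    """
    x = np.asarray(x, dtype=float)
    o = np.asarray(o, dtype=float)
    n_sessions = x.shape[0] // session_length
    W1s = np.empty((n_sessions, 2, o.shape[1]))
    W0s = np.empty_like(W1s)
    # cumulative sums, updated session by session
    sum_x_o = np.zeros((2, o.shape[1]))
    sum_xbar_o = np.zeros((2, o.shape[1]))
    sum_x = np.zeros(2)
    for s in range(n_sessions):
        lo, hi = s * session_length, (s + 1) * session_length
        xs, os_ = x[lo:hi], o[lo:hi]
        sum_x_o += xs.T @ os_
        sum_xbar_o += (1.0 - xs).T @ os_
        sum_x += xs.sum(axis=0)
        stats = SufficientStats(
            mean_x_o=sum_x_o / hi,
            mean_xbar_o=sum_xbar_o / hi,
            mean_x=sum_x / hi,
            trial_count=hi,
        )
        W1s[s], W0s[s] = weights_fixed_point(stats)
    return W1s, W0s


def weights_to_posterior_A(W1: np.ndarray, W0: np.ndarray) -> np.ndarray:
    """Posterior likelihood encoded by the weights.

    Returns an array of shape (2 ensembles, 2 source levels, n_inputs):
    ``A[e, 1, i] = sig(W1[e, i])`` is the implied P(o_i = 1 | source_e ON)
    and ``A[e, 0, i] = sig(W0[e, i])`` the same for source OFF.  OFF
    observation rows are the complements.
    """
    return np.stack([np.stack([sigmoid(W0[e]), sigmoid(W1[e])]) for e in range(2)])


def factorised_evidence_tensor(W1: np.ndarray, W0: np.ndarray) -> np.ndarray:
    """Expected log likelihood tensor implied by the network weights.

    Builds ln A of shape (n_inputs, 2 obs, 2 s1, 2 s2) that is additive
    across the two sources, ``ln A[i,j,k,l] = ln A1[i,j,k] + ln A2[i,j,l]``
    with A_e the per-ensemble Bernoulli likelihood from
    :func:`weights_to_posterior_A`.  Feeding this tensor to the observer's
    state update reproduces the network's sigmoid response exactly, which
    is the operational content of the network/Bayes equivalence.
    """
    A = weights_to_posterior_A(W1, W0)  # (2, 2, I): [ensemble, source level, input]
    n_inputs = A.shape[2]
    lnA = np.empty((n_inputs, 2, 2, 2))
    ln_on = np.log(A)        # ln P(o=1 | level)
    ln_off = np.log1p(-A)    # ln P(o=0 | level)
    for k in (0, 1):
        for l in (0, 1):
            lnA[:, 1, k, l] = ln_on[0, k] + ln_on[1, l]
            lnA[:, 0, k, l] = ln_off[0, k] + ln_off[1, l]
    return lnA


def ideal_marginal_A(A: MixingMatrix, prior: StatePrior) -> np.ndarray:
    """Bayes-ideal counterpart of :func:`weights_to_posterior_A`.

    Marginal ON probabilities P(o_i = 1 | s_e = v), averaging the true
    likelihood over the other source's prior; shape (2, 2, n_inputs).
    """
    on = A.entries[:, 1]  # (I, 2, 2)
    p1, p2 = prior.d1
    out = np.empty((2, 2, A.n_inputs))
    for v in (0, 1):
        out[0, v] = on[:, v, 1] * p2 + on[:, v, 0] * (1.0 - p2)
        out[1, v] = on[:, 1, v] * p1 + on[:, 0, v] * (1.0 - p1)
    return out


def posterior_A_error(A_hat: np.ndarray, A_ideal: np.ndarray) -> np.ndarray:
    """Normalised squared error per likelihood column.

    Both arguments have shape (2 ensembles, 2 source levels, n_inputs);
    each of the four (ensemble, level) vectors over inputs is one column,
    scored as ||A_hat - A_ideal||^2 / ||A_ideal||^2.  Returns the four
    errors flattened (ensemble-major).
    """
    A_hat = np.asarray(A_hat, dtype=float)
    A_ideal = np.asarray(A_ideal, dtype=float)
    if A_hat.shape != A_ideal.shape:
        raise ValueError("shape mismatch between estimated and ideal A")
    num = ((A_hat - A_ideal) ** 2).sum(axis=-1)
    den = (A_ideal**2).sum(axis=-1)
    if np.any(den == 0.0):
        raise ValueError("zero-norm ideal column")
    return (num / den).reshape(-1)


def empirical_free_energy(
    x: np.ndarray,
    o: np.ndarray,
    W1_sessions: np.ndarray,
    W0_sessions: np.ndarray,
    phi: ThresholdFactors,
    session_length: int = 256,
) -> np.ndarray:
    """Per-session variational free energy of the observed responses.

    Substitutes the observed x of each session, with that session's
    estimated weights, into the network cost (integration constant
    omitted).  Report changes from session 1 to compare runs.
    """
    x = np.asarray(x, dtype=float)
    o = np.asarray(o, dtype=float)
    n_sessions = len(W1_sessions)
    F = np.empty(n_sessions)
    for s in range(n_sessions):
        lo, hi = s * session_length, (s + 1) * session_length
        F[s] = cost_function(
            x[lo:hi], o[lo:hi], W1_sessions[s], W0_sessions[s], phi.phi1, phi.phi0
        )
    return F


@dataclass
class FreeEnergyLandscape:
    """F over a grid of two scalar connectivity coordinates.

    The coordinates are sigmoid-space excitatory weights: axis 1 is the
    common strength from the first input group to ensemble 1, axis 2 the
    strength from the second group to ensemble 1.  Ensemble 2 mirrors
    ensemble 1 (groups swapped) and inhibitory weights are tied to the
    complements, so the construction is symmetric under swapping the axes.
    """

    coord1: np.ndarray  # grid values along axis 1, in (0, 1)
    coord2: np.ndarray
    F: np.ndarray       # (len(coord1), len(coord2))
    phi: ThresholdFactors
    stimuli: np.ndarray

    def evaluate(self, c1: float, c2: float) -> float:
        """F at arbitrary coordinates (responses at their fixed point)."""
        return _landscape_F(c1, c2, self.phi, self.stimuli)

    def project(self, W1: np.ndarray) -> tuple[float, float]:
        """Map a weight matrix to landscape coordinates.

        Mean sigmoid-space excitatory weight from each input group to
        ensemble 1.
        """
        half = W1.shape[1] // 2
        s = sigmoid(W1)
        return float(s[0, :half].mean()), float(s[0, half:].mean())

    def argmin(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmin(self.F), self.F.shape)
        return float(self.coord1[i]), float(self.coord2[j])


def _landscape_weights(
    c1: float, c2: float, n_inputs: int
) -> tuple[np.ndarray, np.ndarray]:
    if not (0.0 < c1 < 1.0 and 0.0 < c2 < 1.0):
        raise ValueError("landscape coordinates must lie in (0, 1)")
    half = n_inputs // 2
    s1 = np.empty((2, n_inputs))
    s1[0, :half] = c1
    s1[0, half:] = c2
    s1[1, :half] = c2
    s1[1, half:] = c1
    W1 = logit(s1)
    W0 = logit(1.0 - s1)  # inhibitory tied to the complement
    return W1, W0


def _landscape_F(
    c1: float, c2: float, phi: ThresholdFactors, stimuli: np.ndarray
) -> float:
    W1, W0 = _landscape_weights(c1, c2, stimuli.shape[1])
    h = net_threshold(W1, W0, phi.phi1, phi.phi0)
    x = response_fixed_point(stimuli, W1 - W0, h)
    return cost_function(x, stimuli, W1, W0, phi.phi1, phi.phi0)


def write_reconstructed_model_json(
    path,
    phi: ThresholdFactors,
    W1_sessions: np.ndarray,
    W0_sessions: np.ndarray,
) -> None:
    """Threshold factors, implied prior and per-session weights as JSON."""
    import json

    payload = {
        "phi1": phi.phi1.tolist(),
        "phi0": phi.phi0.tolist(),
        "d_hat": phi.d_hat.tolist(),
        "W1_sessions": np.asarray(W1_sessions).tolist(),
        "W0_sessions": np.asarray(W0_sessions).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_landscape_csv(path, landscape: "FreeEnergyLandscape") -> None:
    """Flat CSV of the free-energy grid: coord1, coord2, F."""
    import pandas as pd

    c1, c2 = np.meshgrid(landscape.coord1, landscape.coord2, indexing="ij")
    pd.DataFrame(
        {"coord1": c1.ravel(), "coord2": c2.ravel(), "F": landscape.F.ravel()}
    ).to_csv(path, index=False)


def landscape_projection(
    phi: ThresholdFactors,
    stimuli: np.ndarray,
    coord1: np.ndarray | None = None,
    coord2: np.ndarray | None = None,
) -> FreeEnergyLandscape:
    """Theoretical free-energy landscape over two connectivity coordinates.

    At each grid node the responses are set to their fixed point given the
    node's weights and ``phi`` (free energy minimised over x), evaluated on
    the supplied stimuli (typically the repeated session sequence).
    """
    if coord1 is None:
        coord1 = np.linspace(0.05, 0.95, 19)
    if coord2 is None:
        coord2 = np.linspace(0.05, 0.95, 19)
    coord1 = np.asarray(coord1, dtype=float)
    coord2 = np.asarray(coord2, dtype=float)
    if coord1.size == 0 or coord2.size == 0:
        raise ValueError("empty landscape grid")
    stimuli = np.asarray(stimuli, dtype=float)
    F = np.empty((coord1.size, coord2.size))
    for i, c1 in enumerate(coord1):
        for j, c2 in enumerate(coord2):
            F[i, j] = _landscape_F(c1, c2, phi, stimuli)
    return FreeEnergyLandscape(coord1=coord1, coord2=coord2, F=F, phi=phi, stimuli=stimuli)
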