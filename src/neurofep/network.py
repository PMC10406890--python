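"""Canonical rate-coding neural network and its reverse-engineered cost.

Two neural ensembles receive 32 binary inputs.  The response dynamics are

    dx/dt  propto  -sig^{-1}(x) + W o + h,

whose fixed point is the sigmoid response ``x = sig(W o + h)``.  The net
weight splits into excitatory and inhibitory parts, ``W = W1 - W0``, and
the firing threshold decomposes as ``h_l = ln(1 - sig(W_l)) . 1 + phi_l``
with threshold factors ``phi_l`` (the network's implicit log state prior).

Integrating the dynamics over x yields a cost function L whose gradient
descent reproduces both the response dynamics (-dL/dx) and a
Hebbian/homeostatic plasticity rule (-(1/t) dL/dW); the weight fixed point
of that rule is the elementwise logit of conditional co-activation ratios.
L is identical, term by term, to the variational free energy of a
factorised two-source observer whose likelihood is parameterised by
sig(W1), sig(W0) and whose state prior is exp(phi); see
:mod:`neurofep.reverse` for the mapping.  A weight-dependent integration
constant is omitted from L throughout (it is constant in x and sub-linear
in t, so session differences are unaffected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import RESPONSE_EPS, logit, sigmoid, xlogx

__all__ = [
    "SufficientStats",
    "NetworkTrainingResult",
    "threshold_from_weights",
    "net_threshold",
    "response_fixed_point",
    "integrate_dynamics",
    "cost_function",
    "sufficient_stats",
    "plasticity_gradient",
    "weights_fixed_point",
    "simulate_network_training",
    "write_network_trajectory_csv",
    "write_weights_csv",
]

#: default ratio clip before the logit in the weight fixed point
RATIO_EPS = 1e-3


def threshold_from_weights(
    W1: np.ndarray, W0: np.ndarray, phi1: np.ndarray, phi0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Firing thresholds h_l = sum_i ln(1 - sig(W_l)) + phi_l, per ensemble."""
    h1 = np.log1p(-sigmoid(W1)).sum(axis=1) + np.asarray(phi1, dtype=float)
    h0 = np.log1p(-sigmoid(W0)).sum(axis=1) + np.asarray(phi0, dtype=float)
    return h1, h0


def net_threshold(
    W1: np.ndarray, W0: np.ndarray, phi1: np.ndarray, phi0: np.ndarray
) -> np.ndarray:
    """Net threshold h = h1 - h0 entering the response fixed point."""
    h1, h0 = threshold_from_weights(W1, W0, phi1, phi0)
    return h1 - h0


def response_fixed_point(o: np.ndarray, W: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Equilibrium response x = sig(W o + h).

    ``o`` may be a single trial (n_inputs,) or a batch (T, n_inputs); the
    result is clipped infinitesimally inside (0, 1) so the logit stays
    finite.
    """
    o = np.asarray(o, dtype=float)
    net = o @ W.T + h if o.ndim == 2 else W @ o + h
    return np.clip(sigmoid(net), RESPONSE_EPS, 1.0 - RESPONSE_EPS)


def integrate_dynamics(
    o: np.ndarray,
    W: np.ndarray,
    h: np.ndarray,
    x0: np.ndarray,
    step_size: float = 0.1,
    n_steps: int = 500,
) -> np.ndarray:
    """Forward-Euler integration of the leaky dynamics for one trial.

    Converges to :func:`response_fixed_point`; the state is clamped inside
    (0, 1) with a warning should a step overshoot (does not occur at the
    default step size).
    """
    x = np.asarray(x0, dtype=float).copy()
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("x0 must lie strictly inside (0, 1)")
    drive = W @ np.asarray(o, dtype=float) + h
    for _ in range(n_steps):
        x = x + step_size * (-logit(x) + drive)
        if np.any(x <= 0.0) or np.any(x >= 1.0):
            warnings.warn("state left (0, 1) during integration; clamped")
            x = np.clip(x, RESPONSE_EPS, 1.0 - RESPONSE_EPS)
    return x


def cost_function(
    x: np.ndarray,
    o: np.ndarray,
    W1: np.ndarray,
    W0: np.ndarray,
    phi1: np.ndarray,
    phi0: np.ndarray,
) -> float:
    """Reverse-engineered network cost L (nats), summed over trials.

    Per trial: (x; 1-x) . { ln(x; 1-x) - ln([sig W1, 1-sig W1; sig W0,
    1-sig W0]) (o; 1-o) - (phi1; phi0) }.  Responses must lie strictly in
    (0, 1); the integration constant is omitted.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    o = np.atleast_2d(np.asarray(o, dtype=float))
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("responses must lie strictly inside (0, 1)")
    xbar = 1.0 - x
    # evidence per trial and ensemble: W_l o + ln(1 - sig(W_l)) . 1
    lw1 = np.log1p(-sigmoid(W1)).sum(axis=1)
    lw0 = np.log1p(-sigmoid(W0)).sum(axis=1)
    ev1 = o @ W1.T + lw1  # (T, 2)
    ev0 = o @ W0.T + lw0
    entropy = xlogx(x) + xlogx(xbar)
    L = entropy - x * (ev1 + phi1) - xbar * (ev0 + phi0)
    return float(L.sum())


@dataclass(frozen=True)
class SufficientStats:
    """Time averages needed by the plasticity rule and weight fixed point."""

    mean_x_o: np.ndarray      # <x o^T>, (2, n_inputs)
    mean_xbar_o: np.ndarray   # <(1-x) o^T>
    mean_x: np.ndarray        # <x>, (2,)
    trial_count: int

    @property
    def mean_xbar(self) -> np.ndarray:
        return 1.0 - self.mean_x


def sufficient_stats(x: np.ndarray, o: np.ndarray) -> SufficientStats:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    o = np.atleast_2d(np.asarray(o, dtype=float))
    if x.shape[0] != o.shape[0]:
        raise ValueError("x and o disagree on trial count")
    n = x.shape[0]
    if n < 1:
        raise ValueError("at least one trial required")
    return SufficientStats(
        mean_x_o=x.T @ o / n,
        mean_xbar_o=(1.0 - x).T @ o / n,
        mean_x=x.mean(axis=0),
        trial_count=n,
    )


def plasticity_gradient(
    stats: SufficientStats, W1: np.ndarray, W0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hebbian + homeostatic weight increments, -(1/t) dL/dW_l.

    dW1 = <x o^T> - <x> sig(W1),  dW0 = <(1-x) o^T> - <1-x> sig(W0)
    (elementwise product along the ensemble axis).
    """
    d1 = stats.mean_x_o - stats.mean_x[:, None] * sigmoid(W1)
    d0 = stats.mean_xbar_o - stats.mean_xbar[:, None] * sigmoid(W0)
    return d1, d0


def weights_fixed_point(
    stats: SufficientStats, clip_eps: float = RATIO_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Weights at which the plasticity gradient vanishes.

    W1 = logit(<x o^T> / <x>), W0 = logit(<(1-x) o^T> / <1-x>), with the
    ratios clipped to [clip_eps, 1 - clip_eps] so deterministic couplings
    and silent ensembles keep the weights finite (silent ensembles are
    flagged with a warning).
    """
    denom1 = stats.mean_x[:, None]
    denom0 = stats.mean_xbar[:, None]
    if np.any(denom1 <= 0.0) or np.any(denom0 <= 0.0):
        warnings.warn("silent or saturated ensemble: ratios set from clip floor")
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(denom1 > 0.0, stats.mean_x_o / np.maximum(denom1, 1e-300), 0.0)
        r0 = np.where(denom0 > 0.0, stats.mean_xbar_o / np.maximum(denom0, 1e-300), 0.0)
    r1 = np.clip(r1, clip_eps, 1.0 - clip_eps)
    r0 = np.clip(r0, clip_eps, 1.0 - clip_eps)
    return logit(r1), logit(r0)


@dataclass
class NetworkTrainingResult:
    """Trajectory of a training simulation."""

    x: np.ndarray              # (T, 2) per-trial equilibrium responses
    W1_sessions: np.ndarray    # (S, 2, n_inputs), weights after each session
    W0_sessions: np.ndarray
    cost_sessions: np.ndarray  # (S,) L of each session, weights in force then
    phi1: np.ndarray
    phi0: np.ndarray


def write_network_trajectory_csv(
    path, result: "NetworkTrainingResult", session_length: int = 256
) -> None:
    """CSV of per-trial equilibrium responses: session, trial, x1, x2."""
    import pandas as pd

    n = result.x.shape[0]
    pd.DataFrame(
        {
            "session": np.arange(n) // session_length + 1,
            "trial": np.arange(n) % session_length + 1,
            "x1": result.x[:, 0],
            "x2": result.x[:, 1],
        }
    ).to_csv(path, index=False)


def write_weights_csv(path, W1: np.ndarray, W0: np.ndarray) -> None:
    """One session's weights as CSV rows labelled by matrix and ensemble."""
    import pandas as pd

    rows = []
    for name, W in (("W1", W1), ("W0", W0)):
        for e in range(W.shape[0]):
            rows.append([name, e + 1, *W[e]])
    cols = ["matrix", "ensemble"] + [f"o_{i + 1:02d}" for i in range(W1.shape[1])]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def simulate_network_training(
    stimuli: np.ndarray,
    phi1: np.ndarray,
    phi0: np.ndarray,
    session_length: int = 256,
    w_init: tuple[np.ndarray, np.ndarray] | None = None,
    w_init_sigma: float = 0.01,
    w_init_bias: float = 0.1,
    plasticity_rate: float = 1.0,
    lambda_w: float = 1280.0,
    rng: np.random.Generator | int | None = 0,
    clip_eps: float = RATIO_EPS,
) -> NetworkTrainingResult:
    """Train the network on a stimulus sequence.

    Per trial the response is the equilibrium ``sig(W o + h)``; once per
    session the weights jump toward the fixed point of the plasticity rule
    evaluated on cumulative-from-start sufficient statistics (fast
    inference, slow learning).  The statistics are seeded with
    pseudo-counts of weight ``lambda_w`` around the initial weights: the
    inverse learning rate, i.e. the insensitivity of the weights to
    plasticity (it maps onto the initial concentration of the implicit
    Dirichlet parameter prior).  The default of 1280 trials-equivalent
    spreads learning out over the first tens of sessions rather than
    letting the first sessions jump straight to the data fixed point.
    ``plasticity_rate`` in (0, 1] additionally scales the per-session step
    in sigmoid space (1 = full step; values below 1 emulate partially
    blocked plasticity).

    Weights start near zero: i.i.d. Gaussian with ``w_init_sigma``, plus a
    small symmetry-breaking excitatory bias ``w_init_bias`` aligning
    ensemble 1 with the first input group and ensemble 2 with the second
    (the ensembles stand for source-preferring populations, which are
    defined by that very preference).
    """
    stimuli = np.asarray(stimuli, dtype=float)
    n_trials, n_inputs = stimuli.shape
    phi1 = np.asarray(phi1, dtype=float)
    phi0 = np.asarray(phi0, dtype=float)
    if not 0.0 < plasticity_rate <= 1.0:
        raise ValueError("plasticity_rate must lie in (0, 1]")
    if lambda_w < 0.0:
        raise ValueError("lambda_w must be nonnegative")
    if w_init is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        W1 = rng.normal(0.0, w_init_sigma, (2, n_inputs))
        W0 = rng.normal(0.0, w_init_sigma, (2, n_inputs))
        half = n_inputs // 2
        W1[0, :half] += w_init_bias
        W1[1, half:] += w_init_bias
    else:
        W1, W0 = (np.asarray(w, dtype=float).copy() for w in w_init)

    n_sessions = int(np.ceil(n_trials / session_length))
    x_all = np.empty((n_trials, 2))
    W1_sessions = np.empty((n_sessions, 2, n_inputs))
    W0_sessions = np.empty((n_sessions, 2, n_inputs))
    cost_sessions = np.empty(n_sessions)
    # cumulative statistics, seeded with lambda_w pseudo-counts at the
    # initial weights (prior numerators lambda * sig(W_init), denominators
    # lambda, matching the implicit Dirichlet concentrations)
    num1 = lambda_w * sigmoid(W1)
    num0 = lambda_w * sigmoid(W0)
    den1 = np.full(2, float(lambda_w))
    den0 = np.full(2, float(lambda_w))
    for s in range(n_sessions):
        lo, hi = s * session_length, min((s + 1) * session_length, n_trials)
        o = stimuli[lo:hi]
        h = net_threshold(W1, W0, phi1, phi0)
        x = response_fixed_point(o, W1 - W0, h)
        x_all[lo:hi] = x
        cost_sessions[s] = cost_function(x, o, W1, W0, phi1, phi0)
        num1 += x.T @ o
        num0 += (1.0 - x).T @ o
        den1 += x.sum(axis=0)
        den0 += (1.0 - x).sum(axis=0)
        r1 = np.clip(num1 / den1[:, None], clip_eps, 1.0 - clip_eps)
        r0 = np.clip(num0 / den0[:, None], clip_eps, 1.0 - clip_eps)
        W1_fp, W0_fp = logit(r1), logit(r0)
        if plasticity_rate >= 1.0:
            W1, W0 = W1_fp, W0_fp
        else:
            # partial step toward the fixed point, in sigmoid space
            s1 = sigmoid(W1) + plasticity_rate * (sigmoid(W1_fp) - sigmoid(W1))
            s0 = sigmoid(W0) + plasticity_rate * (sigmoid(W0_fp) - sigmoid(W0))
            W1 = logit(np.clip(s1, clip_eps, 1.0 - clip_eps))
            W0 = logit(np.clip(s0, clip_eps, 1.0 - clip_eps))
        W1_sessions[s] = W1
        W0_sessions[s] = W0
    return NetworkTrainingResult(
        x=x_all,
        W1_sessions=W1_sessions,
        W0_sessions=W0_sessions,
        cost_sessions=cost_sessions,
        phi1=phi1,
        phi0=phi0,
    )
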