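"""Prediction of responses and plasticity from initial sessions only.

Given the threshold factors and effective connectivity estimated from an
initial window (default: the first 10 sessions), the subsequent sessions
are predicted with no further reference to the data: per session the
predicted response is the network fixed point ``x^P = sig(W^P o + h^P)``,
and the predicted weights are updated to the plasticity fixed point of the
cumulative *predicted* statistics, seeded with pseudo-counts of weight
``lambda_w`` around the initial estimate (the inverse learning rate; it
plays the role of the initial Dirichlet concentration of the implicit
parameter prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import logit, sigmoid
from .network import RATIO_EPS, net_threshold, response_fixed_point
from .reverse import (
    ThresholdFactors,
    estimate_effective_connectivity,
    estimate_threshold_factors,
)

__all__ = [
    "PredictionConfig",
    "PredictedTrajectory",
    "predict_trajectory",
    "weight_prediction_error",
    "response_prediction_error",
    "response_prediction_correlation",
    "write_predicted_trajectory_csv",
]


@dataclass(frozen=True)
class PredictionConfig:
    """Settings for data-free forward prediction.

    ``lambda_w`` defaults to the number of trials in the initial window
    (10 sessions x 256 trials): the initial weight estimate enters the
    running averages with exactly the evidential weight of the data that
    produced it.
    """

    n_init_sessions: int = 10
    lambda_w: float = 2560.0
    session_length: int = 256
    clip_eps: float = RATIO_EPS

    def __post_init__(self) -> None:
        if self.n_init_sessions < 1:
            raise ValueError("n_init_sessions must be >= 1")
        if not self.lambda_w > 0:
            raise ValueError("lambda_w must be positive")


@dataclass
class PredictedTrajectory:
    """Predicted responses and weights for sessions after the window."""

    x_pred: np.ndarray          # (T_pred, 2), sessions n_init+1 .. end
    W1_sessions: np.ndarray     # (S_pred, 2, n_inputs) after each session
    W0_sessions: np.ndarray
    W1_init: np.ndarray         # estimates from the initial window
    W0_init: np.ndarray
    phi: ThresholdFactors
    config: PredictionConfig
    first_predicted_session: int = field(default=11)  # 1-based


def predict_trajectory(
    x: np.ndarray,
    stimuli: np.ndarray,
    cfg: PredictionConfig = PredictionConfig(),
    phi: ThresholdFactors | None = None,
) -> PredictedTrajectory:
    """Predict sessions after the initial window from that window alone.

    Only ``x`` rows inside the window are read; the remainder of the
    recording never enters the computation (replacing it with noise leaves
    the prediction bit-identical).  The stimuli, which are part of the
    experimental design, are used for all sessions.  ``phi`` overrides the
    window estimate of the threshold factors (e.g. for sensitivity
    analyses of prior mis-specification).
    """
    x = np.asarray(x, dtype=float)
    stimuli = np.asarray(stimuli, dtype=float)
    sl = cfg.session_length
    n_sessions = stimuli.shape[0] // sl
    n_init = cfg.n_init_sessions
    if n_init >= n_sessions:
        raise ValueError("initial window covers the whole recording")
    window = slice(0, n_init * sl)
    if phi is None:
        phi = estimate_threshold_factors(x[window], n_init, sl)
    W1, W0 = estimate_effective_connectivity(x[window], stimuli[window], None, sl)
    W1_init, W0_init = W1.copy(), W0.copy()

    lam = cfg.lambda_w
    # pseudo-counts: numerators lam * sig(W_init), denominators lam
    num1 = lam * sigmoid(W1_init)
    num0 = lam * sigmoid(W0_init)
    den1 = np.full(2, lam)
    den0 = np.full(2, lam)

    n_pred = n_sessions - n_init
    x_pred = np.empty((n_pred * sl, 2))
    W1_sessions = np.empty((n_pred, 2, stimuli.shape[1]))
    W0_sessions = np.empty_like(W1_sessions)
    for k in range(n_pred):
        lo = (n_init + k) * sl
        o = stimuli[lo : lo + sl]
        h = net_threshold(W1, W0, phi.phi1, phi.phi0)
        xp = response_fixed_point(o, W1 - W0, h)
        x_pred[k * sl : (k + 1) * sl] = xp
        num1 += xp.T @ o
        num0 += (1.0 - xp).T @ o
        den1 += xp.sum(axis=0)
        den0 += (1.0 - xp).sum(axis=0)
        r1 = np.clip(num1 / den1[:, None], cfg.clip_eps, 1.0 - cfg.clip_eps)
        r0 = np.clip(num0 / den0[:, None], cfg.clip_eps, 1.0 - cfg.clip_eps)
        W1, W0 = logit(r1), logit(r0)
        W1_sessions[k] = W1
        W0_sessions[k] = W0
    return PredictedTrajectory(
        x_pred=x_pred,
        W1_sessions=W1_sessions,
        W0_sessions=W0_sessions,
        W1_init=W1_init,
        W0_init=W0_init,
        phi=phi,
        config=cfg,
        first_predicted_session=n_init + 1,
    )


def write_predicted_trajectory_csv(path, pred: PredictedTrajectory) -> None:
    """CSV of predicted responses: session, trial, x1_pred, x2_pred."""
    import pandas as pd

    sl = pred.config.session_length
    n = pred.x_pred.shape[0]
    first = pred.first_predicted_session
    pd.DataFrame(
        {
            "session": np.arange(n) // sl + first,
            "trial": np.arange(n) % sl + 1,
            "x1_pred": pred.x_pred[:, 0],
            "x2_pred": pred.x_pred[:, 1],
        }
    ).to_csv(path, index=False)


def weight_prediction_error(
    W1_pred: np.ndarray,
    W0_pred: np.ndarray,
    W1_est: np.ndarray,
    W0_est: np.ndarray,
) -> float:
    """Normalised squared weight error, compared in sigmoid space.

    ||(sig W1_pred, sig W0_pred) - (sig W1_est, sig W0_est)||_F^2 divided
    by ||(sig W1_est, sig W0_est)||_F^2.
    """
    if W1_pred.shape != W1_est.shape or W0_pred.shape != W0_est.shape:
        raise ValueError("shape mismatch between predicted and estimated weights")
    p = np.concatenate([sigmoid(W1_pred).ravel(), sigmoid(W0_pred).ravel()])
    e = np.concatenate([sigmoid(W1_est).ravel(), sigmoid(W0_est).ravel()])
    den = float(e @ e)
    if den == 0.0:
        raise ValueError("zero-norm estimated weights")
    return float((p - e) @ (p - e)) / den


def response_prediction_error(x: np.ndarray, x_pred: np.ndarray) -> float:
    """err = E[|x_t - x_t^P|^2] / 2 over the aligned trials."""
    x = np.asarray(x, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    if x.shape != x_pred.shape:
        raise ValueError("observed and predicted responses disagree in shape")
    return float(np.mean(np.sum((x - x_pred) ** 2, axis=1)) / 2.0)


def response_prediction_correlation(
    x: np.ndarray, x_pred: np.ndarray, per_session_means: bool = False,
    session_length: int = 256,
) -> float:
    """Pearson correlation between observed and predicted responses.

    By default pools per-trial pairs (both ensembles); with
    ``per_session_means`` correlates per-session mean responses instead.
    """
    x = np.asarray(x, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    if x.shape != x_pred.shape:
        raise ValueError("observed and predicted responses disagree in shape")
    if per_session_means:
        n = x.shape[0] // session_length
        a = x[: n * session_length].reshape(n, session_length, -1).mean(axis=1).ravel()
        b = (
            x_pred[: n * session_length]
            .reshape(n, session_length, -1)
            .mean(axis=1)
            .ravel()
        )
    else:
        a, b = x.ravel(), x_pred.ravel()
    return float(np.corrcoef(a, b)[0, 1])
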