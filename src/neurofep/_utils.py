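"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: floor used inside logarithms (numerical safety; does not affect results
#: at the tolerances the analyses work with)
LOG_EPS = 1e-8

#: floor/ceiling applied to network responses so the logit stays finite
RESPONSE_EPS = 1e-9


def sigmoid(x: np.ndarray | float) -> np.ndarray:
    """Elementwise logistic function 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p: np.ndarray | float) -> np.ndarray:
    """Elementwise inverse sigmoid ln(p / (1 - p)); p must lie in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("logit requires values strictly inside (0, 1)")
    return np.log(p) - np.log1p(-p)


def xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the convention 0 * ln(0) = 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = p[mask] * np.log(p[mask])
    return out


def safe_log(p: np.ndarray | float, eps: float = LOG_EPS) -> np.ndarray:
    """ln(max(p, eps)): log with a small probability floor."""
    return np.log(np.maximum(np.asarray(p, dtype=float), eps))


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed.

    Components seeded from different children are independently
    reproducible: changing how many draws one component makes does not
    perturb the others.
    """
    seqs = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]
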