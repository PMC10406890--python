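"""POMDP stimulus-generating process.

Two binary hidden sources ``s_t = (s1, s2)`` are drawn i.i.d. from
categorical priors and mixed into 32 binary sensory inputs ``o_t`` through
a likelihood (mixing) tensor ``A``.  The first half of the inputs carries
source 1 with probability ``1 - m`` and source 2 with probability ``m``
(mixing fraction ``m``); the second half is the mirror image.  There are no
state transitions and no actions: each trial is an independent draw.

Conventions
-----------
* The likelihood tensor is indexed ``A[i, j, k, l]`` = P(o_i = j | s1 = k,
  s2 = l) with j, k, l being the *values* 0/1, so ``A[i, 1, 1, 0]`` is the
  probability that input i is ON when only source 1 is ON.
* Joint source states are enumerated in the order (1,1), (1,0), (0,1),
  (0,0) wherever a flat ordering is needed.
* Arrays are 0-based internally; file headers use 1-based labels
  (``o_01`` ... ``o_32``, sessions 1..n).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_STATE_ORDER",
    "StatePrior",
    "MixingMatrix",
    "ExperimentDesign",
    "build_mixing_matrix",
    "sample_sources",
    "sample_observations",
    "generate_experiment",
    "write_stimuli_csv",
    "read_stimuli_csv",
    "write_design",
    "read_design",
]

#: flat ordering of joint source states (s1, s2)
JOINT_STATE_ORDER: tuple[tuple[int, int], ...] = ((1, 1), (1, 0), (0, 1), (0, 0))


@dataclass(frozen=True)
class StatePrior:
    """Categorical prior over each binary source; P(s_j = 1) per source."""

    d1: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        for p in self.d1:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prior probability {p} outside [0, 1]")

    @property
    def d0(self) -> tuple[float, float]:
        return tuple(1.0 - p for p in self.d1)

    def log(self, eps: float = 1e-12) -> np.ndarray:
        """ln D as a (2 sources, 2 values) array; column v is ln P(s = v)."""
        out = np.empty((2, 2))
        for j, p in enumerate(self.d1):
            out[j, 1] = np.log(max(p, eps))
            out[j, 0] = np.log(max(1.0 - p, eps))
        return out


@dataclass(frozen=True)
class MixingMatrix:
    """Likelihood tensor A[i, j, k, l] = P(o_i = j | s1 = k, s2 = l)."""

    entries: np.ndarray
    mix_fraction: float

    @property
    def n_inputs(self) -> int:
        return self.entries.shape[0]

    @property
    def left_group(self) -> np.ndarray:
        """Indices of inputs dominated by source 1 (first half)."""
        return np.arange(self.n_inputs // 2)

    @property
    def right_group(self) -> np.ndarray:
        """Indices of inputs dominated by source 2 (second half)."""
        return np.arange(self.n_inputs // 2, self.n_inputs)

    def on_probability(self, s1: int, s2: int) -> np.ndarray:
        """P(o_i = 1 | s1, s2) for every input i."""
        return self.entries[:, 1, s1, s2]


def build_mixing_matrix(mix_fraction: float, n_inputs: int = 32) -> MixingMatrix:
    """Construct the standard two-group mixing tensor.

    For mixing fraction ``m``, ON probabilities over joint states
    (1,1), (1,0), (0,1), (0,0) are ``(1, 1-m, m, 0)`` for the first half of
    the inputs and ``(1, m, 1-m, 0)`` for the second half; OFF rows are the
    complements.  ``m = 0`` is the unmixed (easily separable) condition and
    ``m = 0.5`` the uniformly mixed (inseparable) one.
    """
    if not 0.0 <= mix_fraction <= 0.5:
        raise ValueError(f"mix_fraction {mix_fraction} outside [0, 0.5]")
    if n_inputs % 2 != 0:
        raise ValueError(f"n_inputs must be even, got {n_inputs}")
    m = float(mix_fraction)
    entries = np.empty((n_inputs, 2, 2, 2))
    half = n_inputs // 2
    # ON probabilities indexed [k, l]
    left_on = np.array([[0.0, m], [1.0 - m, 1.0]])   # [s1, s2]
    right_on = np.array([[0.0, 1.0 - m], [m, 1.0]])
    entries[:half, 1] = left_on
    entries[half:, 1] = right_on
    entries[:, 0] = 1.0 - entries[:, 1]
    return MixingMatrix(entries=entries, mix_fraction=m)


@dataclass(frozen=True)
class ExperimentDesign:
    """Stimulation protocol: sessions of repeated trial sequences.

    The default emulates the standard protocol: 100 sessions of the same
    256-trial random sequence (``repeat_identical_sequence=True``), 32
    inputs mixed at 25%, balanced source priors.
    """

    n_sessions: int = 100
    trials_per_session: int = 256
    n_inputs: int = 32
    mix_fraction: float = 0.25
    state_prior: StatePrior = field(default_factory=StatePrior)
    seed: int = 0
    repeat_identical_sequence: bool = True

    def __post_init__(self) -> None:
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    def with_seed(self, seed: int) -> "ExperimentDesign":
        return replace(self, seed=seed)


def sample_sources(
    prior: StatePrior, n_trials: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Sample an (n_trials, 2) binary source matrix, i.i.d. across trials
    and mutually independent across sources."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = np.asarray(prior.d1)
    return (rng.random((n_trials, 2)) < p).astype(np.int8)


def sample_observations(
    sources: np.ndarray, A: MixingMatrix, rng: np.random.Generator | int
) -> np.ndarray:
    """Sample stimuli o_t ~ Bernoulli(A[i, 1, s1, s2]) given sources."""
    sources = np.asarray(sources)
    if sources.ndim != 2 or sources.shape[1] != 2:
        raise ValueError(f"sources must be (n_trials, 2), got {sources.shape}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    on = A.entries[:, 1, :, :]  # (I, 2, 2)
    probs = on[:, sources[:, 0], sources[:, 1]].T  # (T, I)
    return (rng.random(probs.shape) < probs).astype(np.int8)


def generate_experiment(
    design: ExperimentDesign,
) -> tuple[np.ndarray, np.ndarray, MixingMatrix]:
    """Sample the full source/stimulus sequence for a design.

    Returns ``(sources, stimuli, A)`` with sources of shape (n_trials, 2)
    and stimuli of shape (n_trials, n_inputs).  When
    ``repeat_identical_sequence`` is set, every session replays the
    session-1 sequence bit-exactly.
    """
    A = build_mixing_matrix(design.mix_fraction, design.n_inputs)
    rng_s, rng_o = np.random.SeedSequence(design.seed).spawn(2)
    rng_s = np.random.default_rng(rng_s)
    rng_o = np.random.default_rng(rng_o)
    if design.repeat_identical_sequence:
        s = sample_sources(design.state_prior, design.trials_per_session, rng_s)
        o = sample_observations(s, A, rng_o)
        sources = np.tile(s, (design.n_sessions, 1))
        stimuli = np.tile(o, (design.n_sessions, 1))
    else:
        sources = sample_sources(design.state_prior, design.n_trials, rng_s)
        stimuli = sample_observations(sources, A, rng_o)
    return sources, stimuli, A


# ---------------------------------------------------------------------------
# serialization


def _stimulus_columns(n_inputs: int) -> list[str]:
    return [f"o_{i + 1:02d}" for i in range(n_inputs)]


def write_stimuli_csv(
    path: str | Path,
    design: ExperimentDesign,
    sources: np.ndarray,
    stimuli: np.ndarray,
) -> None:
    """Write sources and stimuli as a flat CSV.

    Columns: session, trial (both 1-based), s1, s2, o_01..o_NN (0/1).
    """
    sources = np.asarray(sources)
    stimuli = np.asarray(stimuli)
    if sources.shape[0] != stimuli.shape[0]:
        raise ValueError("sources and stimuli disagree on trial count")
    n = sources.shape[0]
    tps = design.trials_per_session
    frame = pd.DataFrame(
        {
            "session": np.repeat(np.arange(n // tps if n else 0) + 1, tps)[:n]
            if n
            else np.array([], dtype=int),
            "trial": (np.arange(n) % tps) + 1,
            "s1": sources[:, 0] if n else np.array([], dtype=int),
            "s2": sources[:, 1] if n else np.array([], dtype=int),
        }
    )
    for j, col in enumerate(_stimulus_columns(stimuli.shape[1] if n else design.n_inputs)):
        frame[col] = stimuli[:, j] if n else np.array([], dtype=int)
    frame.to_csv(path, index=False)


def read_stimuli_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a stimuli CSV back into (sources, stimuli) integer arrays."""
    frame = pd.read_csv(path)
    o_cols = [c for c in frame.columns if c.startswith("o_")]
    sources = frame[["s1", "s2"]].to_numpy(dtype=np.int8)
    stimuli = frame[o_cols].to_numpy(dtype=np.int8)
    return sources, stimuli


def write_design(path: str | Path, design: ExperimentDesign) -> None:
    payload = {
        "n_sessions": design.n_sessions,
        "trials_per_session": design.trials_per_session,
        "n_inputs": design.n_inputs,
        "mix_fraction": design.mix_fraction,
        "d1_source1": design.state_prior.d1[0],
        "d1_source2": design.state_prior.d1[1],
        "seed": design.seed,
        "repeat_identical_sequence": design.repeat_identical_sequence,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_design(path: str | Path) -> ExperimentDesign:
    payload = json.loads(Path(path).read_text())
    return ExperimentDesign(
        n_sessions=payload["n_sessions"],
        trials_per_session=payload["trials_per_session"],
        n_inputs=payload["n_inputs"],
        mix_fraction=payload["mix_fraction"],
        state_prior=StatePrior((payload["d1_source1"], payload["d1_source2"])),
        seed=payload["seed"],
        repeat_identical_sequence=payload["repeat_identical_sequence"],
    )
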