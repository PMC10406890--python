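"""Shared fixtures: small experiments and cached control-condition runs."""

from __future__ import annotations

import numpy as np
import pytest

from neurofep.generative import ExperimentDesign, generate_experiment
from neurofep.pipeline import run_full_pipeline
from neurofep.synthetic import (
    SyntheticConfig,
    classify_electrodes,
    condition_design,
    ensemble_responses,
    generate_recording,
)


@pytest.fixture(scope="session")
def small_experiment():
    """A short (8-session) repeated-sequence experiment."""
    design = ExperimentDesign(n_sessions=8, seed=123)
    sources, stimuli, A = generate_experiment(design)
    return design, sources, stimuli, A


@pytest.fixture(scope="session")
def control_recording():
    """One full-length control recording with classification and responses."""
    design = condition_design("control", seed=4)
    rec = generate_recording(design, SyntheticConfig())
    cls = classify_electrodes(rec)
    x = ensemble_responses(rec, cls)
    return rec, cls, x


@pytest.fixture(scope="session")
def control_pipeline_runs():
    """Ten seeded control-condition end-to-end runs (shared across tests)."""
    return [run_full_pipeline({"seed": seed}) for seed in range(10)]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
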