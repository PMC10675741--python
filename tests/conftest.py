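"""Shared fixtures: a small synthetic cohort and a trained pipeline.

The trained pipeline is session-scoped because training is the most
expensive step; every test that needs a fitted model shares it.  Problem
sizes are scaled down from the clinical protocol (see docs/methods.md):
16 subjects, two activities, 10 training epochs.
"""

import numpy as np
import pytest

from fallrisk.model import ModelConfig
from fallrisk.pipeline import train_on_cohort
from fallrisk.synthetic import SimulationConfig, simulate_cohort
from fallrisk.train import TrainConfig

COHORT_SEED = 7


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        n_subjects=16,
        activities=(("walk", 180.0, 10.0), ("get_up_and_go", 50.0, 15.0)),
        seed=COHORT_SEED,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_pipeline(small_cohort):
    """Encoder + head trained on 20% of the cohort windows."""
    return train_on_cohort(
        small_cohort,
        model_config=ModelConfig(seed=COHORT_SEED),
        train_config=TrainConfig(epochs=10, seed=COHORT_SEED),
        split_seed=COHORT_SEED,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
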