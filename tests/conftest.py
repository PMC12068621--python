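"""Shared fixtures: datasets and desk-scale trained models.

Training fixtures are session-scoped because several acceptance checks read
different aspects of the same trained model (classification performance,
reconstruction error, channel usage, latent geometry).  All runs use the
desk-scale profile (n = 20,000 images, batch 64, gamma = 100, lr 5e-5) with
per-experiment epoch counts chosen at the held-out plateau.
"""

import numpy as np
import pytest
from hypothesis import settings

from corridorvae.data import DatasetSpec, generate_dataset
from corridorvae.recipes import ExperimentRecipe, run_experiment

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

DATA_SEED = 11
TRAIN_SEED = 0


@pytest.fixture(scope="session")
def balanced_ds():
    return generate_dataset(DatasetSpec(20_000, "balanced", seed=DATA_SEED))


@pytest.fixture(scope="session")
def lower_left_ds():
    return generate_dataset(DatasetSpec(20_000, "lower_left_10x", seed=DATA_SEED))


def _train(experiment_id, c_max, dataset, epochs):
    recipe = ExperimentRecipe(experiment_id, c_max=c_max, seed=TRAIN_SEED,
                              epochs=epochs, eval_every=25)
    return run_experiment(recipe, dataset)


@pytest.fixture(scope="session")
def baseline_low(balanced_ds):
    """Unsupervised baseline at Cmax = 0.3 nats."""
    return _train("baseline", 0.3, balanced_ds, epochs=300)


@pytest.fixture(scope="session")
def baseline_high(balanced_ds):
    """Unsupervised baseline at Cmax = 10 nats."""
    return _train("baseline", 10.0, balanced_ds, epochs=300)


@pytest.fixture(scope="session")
def e2m1_low(balanced_ds):
    """Hybrid model, linear head on task T1, Cmax = 0.3 nats."""
    return _train("E2M1", 0.3, balanced_ds, epochs=300)


@pytest.fixture(scope="session")
def e2m4_high(balanced_ds):
    """Hybrid model, nonlinear head on the 25-class task, Cmax = 10 nats."""
    return _train("E2M4", 10.0, balanced_ds, epochs=250)


@pytest.fixture(scope="session")
def e2m5_low(balanced_ds):
    """Multi-task hybrid (all four heads), Cmax = 0.3 nats."""
    return _train("E2M5", 0.3, balanced_ds, epochs=200)


@pytest.fixture(scope="session")
def e1m1_low(lower_left_ds):
    """Frequency-biased model (lower corridor left 10x), Cmax = 0.3 nats."""
    return _train("E1M1", 0.3, lower_left_ds, epochs=300)


@pytest.fixture(scope="session")
def test_split(balanced_ds):
    _, test = balanced_ds.split(0.1, 7)
    return test
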