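"""Shared fixtures: a small synthetic dataset and a trained model.

Session scope keeps the expensive forest fits to a single run; tests that
need different conditions build their own datasets.
"""

from __future__ import annotations

import numpy as np
import pytest

from gram.model import GramDataset, TrainingConfig, train_full
from gram.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(V=150, N=12, n_signal_tfs=4, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_gram_dataset(small_dataset) -> GramDataset:
    return GramDataset(
        bsm=small_dataset.bsm,
        profiles=small_dataset.profiles,
        counts=small_dataset.counts,
    )


@pytest.fixture(scope="session")
def small_training_config() -> TrainingConfig:
    return TrainingConfig(n_trees=120, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_gram_dataset, small_training_config):
    return train_full(small_gram_dataset, small_training_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
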