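"""Shared fixtures: small seeded datasets and trained models, built once."""

import pytest

import fatiguekit as fk
from fatiguekit.network import FatigueCNN, split_dataset
from fatiguekit.preprocess import EpochPreprocessor


@pytest.fixture(scope="session")
def small_recordings():
    """10 epochs per class at all five fatigue levels (15 s each)."""
    return fk.generate_dataset(10, seed=11)


@pytest.fixture(scope="session")
def preprocessed_small(small_recordings):
    return EpochPreprocessor().transform(small_recordings)


@pytest.fixture(scope="session")
def two_class_split():
    """A separable normal-vs-complete-fatigue dataset, split 70/10/20."""
    ds = fk.generate_dataset(40, levels=(0, 4), seed=23)
    eds = EpochPreprocessor().transform(ds)
    return split_dataset(eds, seed=23)


@pytest.fixture(scope="session")
def two_class_models(two_class_split):
    """One trained classifier per activation variant on the 2-class task."""
    train, val, _ = two_class_split
    models = {}
    for variant in ("t2f", "relu", "leaky_relu"):
        clf = FatigueCNN(activation=variant, optimizer="rmsprop",
                         max_epochs=10, patience=10, seed=23)
        clf.fit(train.epochs, train.labels,
                validation_data=(val.epochs, val.labels))
        models[variant] = clf
    return models
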