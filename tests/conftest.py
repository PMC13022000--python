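"""Shared fixtures.

The trained-model fixtures are session-scoped because contrastive training
on the default planted-cluster dataset takes on the order of a minute; every
test that needs a trained projection shares the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from erepoc import fixtures, model

REDUCED_CONFIG = dict(
    train_batches_per_epoch=64,
    val_batches_per_epoch=16,
    patience=10,
    max_epochs=100,
)

ABLATION_HELDOUT = ("HEM", "SAM")


@pytest.fixture(scope="session")
def ablation_heldout():
    return ABLATION_HELDOUT


@pytest.fixture(scope="session")
def default_dataset() -> fixtures.EmbeddingDataset:
    """The default 7-class planted-cluster dataset (n=1400, dim=1280, seed 7)."""
    return fixtures.make_embedding_dataset(fixtures.FixtureSpec())


@pytest.fixture(scope="session")
def trained(default_dataset):
    """Projection trained on the full 7-class dataset (reduced schedule)."""
    cfg = model.TrainingConfig(seed=7, **REDUCED_CONFIG)
    m, history = model.train(default_dataset.embeddings, default_dataset.fingerprints, cfg)
    return m, history


@pytest.fixture(scope="session")
def trained_latents(trained, default_dataset) -> np.ndarray:
    m, _ = trained
    return model.encode(m, default_dataset.embeddings)


@pytest.fixture(scope="session")
def ablation_trained(default_dataset):
    """Projection trained with two ligand classes held out entirely."""
    mask = ~np.isin(default_dataset.labels, ABLATION_HELDOUT)
    cfg = model.TrainingConfig(seed=7, **REDUCED_CONFIG)
    m, _ = model.train(default_dataset.embeddings[mask],
                       default_dataset.fingerprints[mask], cfg)
    return m
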