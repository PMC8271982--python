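"""Shared fixtures: small synthetic datasets and a quickly-overfit model."""

from __future__ import annotations

import numpy as np
import pytest

from skelact import (
    LabeledDataset,
    SkeletonActionCNN,
    TrainingConfig,
    cross_subject_split,
    get_ordering,
)
from skelact.synthetic import CollectionProtocol, generate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """4 subjects × 9 classes × 5 reps = 180 sequences of 64 frames."""
    return generate_dataset(CollectionProtocol(n_subjects=4, master_seed=11))


@pytest.fixture(scope="session")
def encoded_b1(small_dataset) -> LabeledDataset:
    return small_dataset.encode(get_ordering("B1"))


@pytest.fixture(scope="session")
def overfit_results(small_dataset):
    """A model memorizing 20 images (50 epochs, no regularization)."""
    subset = LabeledDataset(small_dataset.samples[:45], small_dataset.classes)
    images = subset.encode(get_ordering("B1"))
    images = LabeledDataset(images.samples[:20], images.classes)
    cfg = TrainingConfig(epochs=50, batch_size=20, weight_decay=0.0, runs=1)
    model = SkeletonActionCNN(images, config=cfg)
    return model.fit(seed=0), images
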