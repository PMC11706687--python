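"""Shared fixtures: synthetic datasets and a session-scoped trained model."""

from __future__ import annotations

import numpy as np
import pytest

from phroot.model import ArchConfig, build_model
from phroot.synthetic import SyntheticConfig, generate_dataset
from phroot.training import TrainConfig, evaluate, train

STUDY_GROUPS = [
    ("Col-0", "mock"),
    ("Col-0", "BL"),
    ("bri1-301", "mock"),
    ("bri1-301", "BL"),
]


def as_pairs(samples):
    """(brightfield, labels) training pairs from synthetic samples."""
    return [
        (s.image.channel("bf405").astype(np.float32), s.mask.labels) for s in samples
    ]


@pytest.fixture(scope="session")
def training_samples():
    """100 synthetic root images at 96 px (25 per study group)."""
    config = SyntheticConfig(image_size=96, seed=101)
    samples, metadata = generate_dataset(config, 25, STUDY_GROUPS)
    return samples, metadata


@pytest.fixture(scope="session")
def trained_setup(training_samples):
    """Tiny U-Net² trained on the 100-image synthetic dataset (80/10/10).

    Returns (model, per-epoch metrics, validation pairs, test pairs).  The
    model carries the best-validation-IoU weights.
    """
    samples, _ = training_samples
    pairs = as_pairs(samples)
    rng = np.random.default_rng(7)
    order = rng.permutation(len(pairs))
    train_pairs = [pairs[i] for i in order[:80]]
    val_pairs = [pairs[i] for i in order[80:90]]
    test_pairs = [pairs[i] for i in order[90:]]
    model = build_model(ArchConfig(scale="tiny"), init_seed=3)
    model, metrics = train(
        model,
        train_pairs,
        val_pairs,
        TrainConfig(epochs=22, batch_size=4, seed=11),
    )
    return model, metrics, val_pairs, test_pairs


@pytest.fixture(scope="session")
def untrained_tiny():
    return build_model(ArchConfig(scale="tiny"), init_seed=0)


@pytest.fixture()
def small_sample():
    config = SyntheticConfig(image_size=64, seed=17)
    from phroot.synthetic import generate_sample

    return generate_sample(config, "Col-0", "mock")
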