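"""Shared fixtures: tiny phantom subjects and pre-trained micro-models."""

from __future__ import annotations

import numpy as np
import pytest

from liver4d.core_io import zscore_normalize
from liver4d.network import ArchConfig, TrainConfig, build_unet, train
from liver4d.phantom import AnatomyParams, make_subject, sample_training_pairs


@pytest.fixture(scope="session")
def subject64():
    """Reference 64^3 subject used by registration-oriented tests."""
    return make_subject(AnatomyParams(), seed=3, grid=64)


@pytest.fixture(scope="session")
def subject32():
    """Small 32^3 subject for fast training tests."""
    return make_subject(
        AnatomyParams(liver_extent_mm=(30.0, 26.0, 32.0), max_si_excursion_mm=10.0),
        seed=1,
        grid=32,
    )


@pytest.fixture(scope="session")
def tiny_training(subject32):
    """Sixty phantom pairs plus subject normalization stats."""
    samples = sample_training_pairs(subject32, 60, seed=2)
    imgs = [s.navigator for s in samples] + [s.label for s in samples]
    imgs.append(subject32.static.voxels)
    _, norm = zscore_normalize(imgs, subject32.subject_id)
    return samples, norm


@pytest.fixture(scope="session")
def trained_model(subject32, tiny_training):
    """A converged micro U-Net on the 32^3 subject (seeded)."""
    samples, norm = tiny_training
    arch = ArchConfig(in_shape=(32, 32, 3), base_filters=4, dropout_rate=0.1)
    model = build_unet(arch, seed=0)
    cfg = TrainConfig(learning_rate=2e-3, epochs=10, batch_size=16, seed=0)
    model, history = train(model, samples[:40], samples[40:], cfg, norm)
    return model, history
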