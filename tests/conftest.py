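"""Shared fixtures.

The trained U-Net is expensive (minutes on one CPU), so it is built once per
session and shared by the model-quality gate and the end-to-end benchmark.
"""

from __future__ import annotations

import numpy as np
import pytest

from clemalign import (
    ImagePlane,
    ModelConfig,
    SceneParams,
    make_training_set,
    train_model,
)
from clemalign.label import REDUCED_TRAIN_PRESET

TRAIN_SEED = 101
HELDOUT_SEED = 777


@pytest.fixture(scope="session")
def trained_model():
    """Depth-3 U-Net trained on 30 synthetic aligned pairs (reduced preset)."""
    pairs = make_training_set(30, SceneParams(), seed=TRAIN_SEED)
    return train_model(pairs, ModelConfig(), REDUCED_TRAIN_PRESET)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_plane(pixels, pixel_size_nm=25.0, **kw) -> ImagePlane:
    return ImagePlane(np.asarray(pixels, dtype=float), pixel_size_nm, **kw)
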