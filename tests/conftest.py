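"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from plax.scene import SceneConfig, generate_scene


def coil_config(k: int) -> SceneConfig:
    """Scene sized for reliable coil rendering at desk scale."""
    return SceneConfig.for_size(384, 512, coil_count=k,
                                cord_length=(380.0, 440.0),
                                cord_halfwidth=(8.0, 9.5))


def train_config(**kw) -> SceneConfig:
    """Small scenes for network training (disc axes stay >= 30 px)."""
    return SceneConfig.for_size(288, 384, **kw)


@pytest.fixture(scope="session")
def fetal_scene():
    return generate_scene(SceneConfig.for_size(384, 512), seed=11)


@pytest.fixture(scope="session")
def maternal_scene():
    return generate_scene(SceneConfig.for_size(384, 512, side="maternal"), seed=12)


@pytest.fixture(scope="session")
def coil_scene():
    return generate_scene(coil_config(6), seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
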