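import matplotlib

matplotlib.use("Agg")

from dataclasses import replace

import numpy as np
import pytest

import actinseg as a


@pytest.fixture(scope="session")
def small_scene():
    """One noiseless 256x256 scene with both pattern classes present."""
    spec = a.SceneSpec(image_shape=(256, 256), seed=3, noise_model="none")
    return a.generate_scene(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    spec = a.SceneSpec(image_shape=(256, 256), seed=11)
    return a.generate_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scene(seed, **overrides):
    spec = replace(a.SceneSpec(image_shape=(256, 256)), seed=seed, **overrides)
    return a.generate_scene(spec)
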