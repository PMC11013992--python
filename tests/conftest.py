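import numpy as np
import pytest

from dfsnet.synthetic import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def minimal_scene():
    """A small noiseless 3-class scene with its geometric recipe."""
    return generate_scene(
        SceneConfig(
            class_set="minimal", points_per_scene=3000, noise_sd=0.0, seed=7
        ),
        with_recipe=True,
    )


@pytest.fixture(scope="session")
def simple_scene():
    """A small 5-class scene at the default noise level."""
    return generate_scene(
        SceneConfig(class_set="simple", points_per_scene=5000, seed=11)
    )
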