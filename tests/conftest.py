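import numpy as np
import pytest
from hypothesis import settings

from tipqc import synthcam

settings.register_profile("deterministic", derandomize=True, max_examples=40)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scene_template() -> synthcam.SceneSpec:
    return synthcam.SceneSpec()


@pytest.fixture(scope="session")
def nominal_render(scene_template):
    """Noise-free 400-step aspiration frame with its ground truth."""
    scene = synthcam.SceneSpec(steps=400.0)
    return synthcam.render(scene)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
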