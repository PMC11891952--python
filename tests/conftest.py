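import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One modest synthetic field reused by pipeline-level tests."""
    from aponecv import SceneSpec, generate_scene

    spec = SceneSpec(shape=(256, 256), n_viable=3, n_apoptotic=1,
                     n_necrotic=2, seed=7)
    stack, truth = generate_scene(spec)
    return stack, truth
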