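import numpy as np
import pytest

from fluorokin.synthetic import SceneConfig, base_bone_mesh, make_scene


@pytest.fixture(scope="session")
def femur_mesh():
    return base_bone_mesh("femur", subdivisions=2)


@pytest.fixture(scope="session")
def tibia_mesh():
    return base_bone_mesh("tibia", subdivisions=2)


@pytest.fixture(scope="session")
def scene128():
    """Desk-scale synthetic knee scene shared across tests (read-only)."""
    return make_scene(SceneConfig(image_size=128), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
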