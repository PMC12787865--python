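import numpy as np
import pytest

from trayvol import MockBackend, PipelineConfig, SceneSpec, ShapeSpec, render_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cap_spec():
    """Standard spherical-cap scene: R=50, h=20 on a tilted 512x512 tray."""
    return SceneSpec(
        grid=(512, 512),
        plane=(0.02, -0.01, 0.3),
        items=(
            ShapeSpec("spherical_cap", {"radius": 50, "height": 20}, (256, 256),
                      label="cap"),
        ),
    )


@pytest.fixture(scope="session")
def cap_scene(cap_spec):
    return render_scene(cap_spec)


@pytest.fixture()
def mock_backend(cap_scene):
    return MockBackend.from_scene(cap_scene)


@pytest.fixture()
def config():
    return PipelineConfig()
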