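import numpy as np
import pytest

from myofuse import (
    RenderParams,
    SceneParams,
    generate_scene,
    render_scene,
    roi_set_from_scene,
)

NOISELESS = RenderParams(psf_sigma_px=0.0, noise_model="none", background_level=0.0)


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneParams(seed=11))


@pytest.fixture(scope="session")
def noiseless_stack(default_scene):
    return render_scene(default_scene, NOISELESS)


@pytest.fixture(scope="session")
def default_rois(default_scene):
    return roi_set_from_scene(default_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
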