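import numpy as np
import pytest

from kelpyield.camera_geometry import CameraModel
from kelpyield.stereo_depth import SgmParams
from kelpyield.synthetic_scene import (
    SceneSpec,
    SheetSpec,
    default_camera,
    render_stereo_set,
)


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def spec_camera():
    """Camera with f = 500 px used by the worked pinhole examples (1x2 m sheet
    at 2.5 m projects to exactly 200 x 400 px)."""
    return CameraModel(
        focal_px_h=500.0, focal_px_v=500.0, cx=160.0, cy=224.0,
        baseline_m=0.095, width=320, height=448,
    )


@pytest.fixture(scope="session")
def sheet_scene(spec_camera):
    """Single 1 m x 2 m fronto-parallel sheet at Z = 2.5 m, noise-free."""
    sheet = SheetSpec(top_anchor=(-0.5, -1.0, 2.5), width_m=1.0, length_m=2.0,
                      texture_seed=11)
    return SceneSpec(
        sheets=(sheet,), camera=spec_camera,
        water_attenuation_beta=0.0, noise_sigma=0.0, rng_seed=5,
    )


@pytest.fixture(scope="session")
def sheet_render(sheet_scene):
    return render_stereo_set(sheet_scene)


@pytest.fixture(scope="session")
def noisy_render(camera):
    """Moderately hazy, noisy single-sheet scene for regression fixtures."""
    sheet = SheetSpec(top_anchor=(-0.8, -1.0, 2.2), width_m=1.6, length_m=2.0,
                      texture_seed=3)
    scene = SceneSpec(
        sheets=(sheet,), camera=camera,
        water_attenuation_beta=0.3, noise_sigma=5.0, rng_seed=17,
    )
    return scene, render_stereo_set(scene)


@pytest.fixture(scope="session")
def fast_sgm():
    """Search range matched to the 1-4 m working band of the render camera."""
    return SgmParams(disparity_range=(0, 24))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
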