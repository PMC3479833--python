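import numpy as np
import pytest

from fogspeed.optics import CalibrationCurve
from fogspeed.scene import SceneFrame, SceneSpec, make_road_scene


@pytest.fixture(scope="session")
def identity_cal() -> CalibrationCurve:
    return CalibrationCurve.identity()


@pytest.fixture(scope="session")
def curved_cal() -> CalibrationCurve:
    """A gently accelerating display curve (a2 > 0) to exercise nonlinearity."""
    return CalibrationCurve(a2=0.001, a1=0.1, a0=1.0, r_squared=0.999)


@pytest.fixture(scope="session")
def road_spec() -> SceneSpec:
    return SceneSpec(width_px=128, height_px=96, horizon_row=32, seed=7)


@pytest.fixture(scope="session")
def road_frame(road_spec) -> SceneFrame:
    return make_road_scene(road_spec)


@pytest.fixture(scope="session")
def balanced_frame() -> SceneFrame:
    """Hand-built frame whose mean brightness equals the fog colour (128).

    With a linear calibration and fog brightness 128, uniform blending of
    this frame scales luminance deviations by exactly (1 - opacity) while
    leaving the mean fixed, giving a closed-form contrast for the
    matching-solver checks.  Depth decreases toward the bottom row.
    """
    spec = SceneSpec(width_px=8, height_px=8, horizon_row=2, texture_contrast=0.0)
    rng = np.random.default_rng(42)
    brightness = rng.uniform(60.0, 196.0, size=(8, 8))
    brightness = brightness - brightness.mean() + 128.0  # exact mean 128
    depth = np.full((8, 8), np.inf)
    for r in range(3, 8):
        depth[r, :] = 0.8 * 8.0 / (r - 2)
    return SceneFrame(brightness=brightness, depth_m=depth, spec=spec)
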