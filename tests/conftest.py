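import numpy as np
import pytest

from gazeval.camera_geometry import CameraModel
from gazeval.core import InstructionSchedule
from gazeval.synthetic_session import SyntheticScenario, dot_layout, render_dots_image


@pytest.fixture
def cam_t2() -> CameraModel:
    return CameraModel(vd_px=1132.4)


@pytest.fixture
def cam_t3() -> CameraModel:
    return CameraModel(vd_px=912.8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def seated_schedule() -> InstructionSchedule:
    from gazeval.synthetic_session import make_protocol

    return make_protocol("seated_chinrest", seed=7)


@pytest.fixture
def clean_chinrest_scenario() -> SyntheticScenario:
    """Noise-free, blink-free, tremor-free seated scenario (exact ground truth)."""
    return SyntheticScenario(
        condition="seated_chinrest",
        device="tobii2",
        tremor_sd_px=0.0,
        seed=3,
    )


@pytest.fixture
def dot_pattern_frame(cam_t2):
    """Rendered ideal nine-dot frame plus its ground-truth layout."""
    layout = dot_layout(cam_t2)
    img = render_dots_image({k: tuple(v) for k, v in layout.items()}, 11.3, cam_t2)
    return img, layout
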