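import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from usnav import calibration as cal
from usnav import phantom as ph
from usnav import transforms as tr

#: centre of the packaged evaluation-phantom reference, mm (world frame)
EVAL_CENTER = np.array([55.34, 90.08, -1008.65])


def random_transform(rng, parent="world", child="tool", translation_scale=100.0):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-translation_scale, translation_scale, 3)
    return tr.from_rotation_translation(R, t, parent, child)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eval_scene():
    return ph.build_eval_phantom(EVAL_CENTER, axis=(0.0, 1.0, 0.0))


@pytest.fixture
def probe_cal():
    """Identity probe calibration with 0.1 mm isotropic pixels."""
    return cal.ProbeCalibration(
        spacing=(0.1, 0.1),
        sono_T_image=tr.identity("sono", "image"),
        residual_rms=0.0,
    )


@pytest.fixture
def centered_probe_pose(probe_cal):
    """Probe pose whose 128x128 image plane passes through the scene centre,
    with the centre projecting to pixel (64, 64)."""
    spacing = probe_cal.spacing
    offset = np.array([64 * spacing[0], 64 * spacing[1], 0.0])
    return tr.translation_transform(EVAL_CENTER - offset, "world", "sono")
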