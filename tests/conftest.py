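import numpy as np
import pytest

from stereofauna import geometry, synthetic


@pytest.fixture(scope="session")
def rig():
    """Default axis-aligned synthetic rig: 120 mm baseline, f = 1400 px."""
    return synthetic.make_rig()


@pytest.fixture(scope="session")
def rect(rig):
    return geometry.rectify(rig)


@pytest.fixture(scope="session")
def distorted_rig():
    """Misaligned rig with lens distortion, to exercise the full model."""
    return synthetic.make_rig(distortion=[-0.1, 0.02, 0.001, -0.001, 0.0],
                              yaw_deg=2.0)


def project_stereo(rig, points):
    """Project left-frame points through both raw cameras."""
    uvl = geometry.project_points(rig.left, points)
    uvr = geometry.project_points(rig.right, points, rig.rotation,
                                  rig.translation)
    return uvl, uvr
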