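import numpy as np
import pytest

from jawdisp.measurements import CrossSection, LandmarkSet


def lm_sagittal(specimen_id="sp", **points):
    """Build a LandmarkSet from 2D sagittal-plane coordinates (x, z)."""
    return LandmarkSet(
        specimen_id=specimen_id,
        **{name: (p[0], 0.0, p[1]) for name, p in points.items()},
    )


def full_landmark_set(specimen_id="sp"):
    """A complete, non-degenerate hand-placed specimen."""
    return LandmarkSet(
        specimen_id=specimen_id,
        jaw_joint=(0.0, 0.0, 0.0),
        coronoid_tip=(0.25, 0.0, 0.3),
        anterior_tip=(1.0, 0.0, 0.05),
        posterior_tip=(-0.15, 0.0, -0.02),
        triturating_posterior=(0.45, 0.0, 0.08),
        width_left=(0.4, 0.5, -0.05),
        width_right=(0.4, -0.5, -0.05),
        trit_width_left=(0.8, 0.07, 0.0),
        trit_width_right=(0.8, -0.07, 0.0),
    )


@pytest.fixture
def specimen():
    return full_landmark_set()


@pytest.fixture
def cross_section():
    return CrossSection(a=0.2, b=0.35)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
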