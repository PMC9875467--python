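import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import palmscreen as ps
from palmscreen.cohort import hand_mask

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """A small but fully default-structured cohort: 10 anemic + 8 non-anemic."""
    return ps.CohortSpec(n_anemic=10, n_non_anemic=8, seed=7, height=64, width=64)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return ps.make_cohort(small_spec)


@pytest.fixture(scope="session")
def ground_truth_mask(small_spec):
    return hand_mask(small_spec.height, small_spec.width)


def uniform_image(rgb, h=40, w=40, patient_id="P-uniform"):
    """A PalmImage filled with one color."""
    pixels = np.tile(np.asarray(rgb, dtype=np.uint8), (h, w, 1))
    return ps.PalmImage(patient_id=patient_id, pixels=pixels)


@pytest.fixture()
def full_frame_crop():
    """Full-frame ROI over a seeded random image (every pixel retained)."""
    rng = np.random.default_rng(42)
    img = ps.PalmImage(
        patient_id="P-rand", pixels=rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
    )
    return ps.RoiCrop.full_frame(img), img
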