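import numpy as np
import pytest

from neolus.quant import Calibration, LUSClip, ROI
from neolus.synthetic import ClipGeometry, CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return ClipGeometry()


@pytest.fixture
def identity_cal():
    return Calibration(intercept=0.0, slope=1.0, r2=1.0)


@pytest.fixture
def small_cohort():
    """Shrunk cohort for fast end-to-end tests (same structure as defaults)."""
    return CohortConfig(
        n_control=3,
        n_elevated=3,
        schedule=(-1.0, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0),
        seed=7,
    )


def make_clip(frames, **kw):
    return LUSClip(frames=np.asarray(frames, dtype=np.uint8), **kw)


@pytest.fixture
def checker_clip():
    """Two-frame clip whose single ROI is half 50s and half 150s."""
    frame = np.zeros((16, 16), dtype=np.uint8)
    frame[:8] = 50
    frame[8:] = 150
    return make_clip(np.stack([frame, frame])), ROI(0, 0, 16, 16)
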