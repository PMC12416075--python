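import numpy as np
import pytest

from larvascreen import (
    BehaviorParams,
    LarvaTrack,
    Thresholds,
    WellGeometry,
    default_schedule,
)
from larvascreen.protocol import FRAME_INTERVAL_S


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def short_schedule():
    """Same 18-period layout compressed to 1-minute periods (180 frames)."""
    return default_schedule(period_min=1.0)


@pytest.fixture(scope="session")
def well():
    return WellGeometry()


@pytest.fixture(scope="session")
def base_params():
    return BehaviorParams()


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


def make_track(x, y, heading, arm="arm", wellid="w000"):
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) * FRAME_INTERVAL_S
    return LarvaTrack(arm, wellid, t, x, y, np.asarray(heading, dtype=float) % 360.0)


def straight_track(n, step, heading_deg=0.0, arm="arm", wellid="w000"):
    """Constant-step straight-line motion (unbounded coordinates; use only
    with features that ignore well geometry)."""
    rad = np.radians(heading_deg)
    d = np.arange(n) * step
    return make_track(
        d * np.cos(rad), d * np.sin(rad), np.full(n, heading_deg % 360.0), arm, wellid
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
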