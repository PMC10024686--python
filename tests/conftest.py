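import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitkit as gk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> gk.GaitParams:
    return gk.GaitParams()


@pytest.fixture(scope="session")
def small_cohort(default_params) -> gk.SimulatedCohort:
    """A 40-cow cohort shared by aggregation/screening tests."""
    return gk.simulate_cohort(default_params, 40, seed=11)


@pytest.fixture
def full_pose() -> gk.CowPose:
    """A fully visible pose on an arched topline, head held high."""
    track = gk.simulate_cow_track(gk.GaitParams(keypoint_noise_sd=0.0), 2, seed=0,
                                  n_frames=1)
    return track.poses[0]


def make_pose(points: dict[str, tuple[float, float]],
              frame_index: int = 0) -> gk.CowPose:
    """Pose with the given points visible and every other key-point absent."""
    visibility = {
        n: gk.Visibility.VISIBLE if n in points else gk.Visibility.ABSENT
        for n in gk.KEYPOINT_NAMES
    }
    return gk.CowPose(points=dict(points), visibility=visibility,
                      frame_index=frame_index)


def grid_pose(frame_index: int = 0, offset: float = 0.0) -> gk.CowPose:
    """All 15 key-points visible at distinct positions."""
    pts = {
        n: (offset + 10.0 * i, offset + 7.0 * ((i * 3) % 15))
        for i, n in enumerate(gk.KEYPOINT_NAMES)
    }
    return make_pose(pts, frame_index)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
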