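import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ivtrack as iv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_trackset(
    rng, n_tracks=20, n_frames=15, dt=0.5, dim=2, labels=None
) -> iv.TrackSet:
    """Plain Gaussian-step tracks for structural/property tests."""
    times = np.arange(n_frames) * dt
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(scale=1.5, size=(n_frames - 1, dim))
        pos = np.vstack([rng.uniform(-50, 50, size=(1, dim)),]).repeat(1, axis=0)
        pos = np.vstack([pos, pos[0] + np.cumsum(steps, axis=0)])
        tracks.append(
            iv.Track(f"t{i:03d}", times, pos, labels=labels or {})
        )
    return iv.TrackSet(tuple(tracks), frame_interval=dt)


@pytest.fixture
def random_trackset(rng):
    return make_random_trackset(rng)


def rigid_motion(trackset: iv.TrackSet, angle=0.7, shift=(13.0, -4.0)) -> iv.TrackSet:
    """Rotate then translate every track of a planar cohort."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    shift = np.asarray(shift)
    moved = tuple(
        iv.Track(t.track_id, t.times, t.positions @ rot.T + shift, t.labels)
        for t in trackset
    )
    return iv.TrackSet(moved, frame_interval=trackset.frame_interval)
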