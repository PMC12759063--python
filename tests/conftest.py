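import numpy as np
import pytest
from hypothesis import settings

from ivtk.tracks_io import Track, TrackPoint

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_track(t, x, y, z=None, track_id="t0", **kw) -> Track:
    zs = z if z is not None else [None] * len(t)
    pts = [TrackPoint(float(ti), float(xi), float(yi), zi if zi is None else float(zi))
           for ti, xi, yi, zi in zip(t, x, y, zs)]
    return Track(track_id=track_id, points=pts, **kw)


@pytest.fixture
def straight_track():
    """100 µm along +x in 10 min, 11 uniform points."""
    t = np.arange(11) * 60.0
    return make_track(t, np.linspace(0, 100, 11), np.zeros(11))


@pytest.fixture
def stationary_track():
    t = np.arange(5) * 10.0
    return make_track(t, np.full(5, 3.0), np.full(5, 4.0))


@pytest.fixture
def random_walk_tracks():
    """100 2D random-walk tracks, uniform 10-s sampling."""
    rng = np.random.default_rng(42)
    tracks = []
    for i in range(100):
        n = rng.integers(10, 60)
        steps = rng.normal(scale=1.5, size=(n, 2))
        pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)]) + 50
        tracks.append(make_track(np.arange(n + 1) * 10.0, pos[:, 0], pos[:, 1],
                                 track_id=f"rw{i}"))
    return tracks
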