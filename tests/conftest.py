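import numpy as np
import pytest

from trackthin.trackio import LOCAL_METRIC, Track


@pytest.fixture
def triangle_track() -> Track:
    """3-4-5 right triangle walked in two 60 s legs (path length 7 m)."""
    return Track("tri", "s1", [0.0, 60.0, 120.0], [0.0, 3.0, 3.0], [0.0, 0.0, 4.0], LOCAL_METRIC)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170710)


@pytest.fixture
def make_random_walk():
    """Factory for planar random-walk tracks on a uniform time grid."""

    def _make(rng: np.random.Generator, n: int = 100, dt: float = 10.0,
              step_sd: float = 3.0, track_id: str = "rw") -> Track:
        t = dt * np.arange(n)
        x = np.cumsum(rng.normal(0, step_sd, n))
        y = np.cumsum(rng.normal(0, step_sd, n))
        return Track(track_id, "s1", t, x, y, LOCAL_METRIC)

    return _make
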