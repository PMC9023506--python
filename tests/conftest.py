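import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from larvascreen import WellGeometry, default_schedule
from larvascreen.synthetic import LarvaTrack


@pytest.fixture(scope="session")
def schedule():
    """The full 1800-frame schedule (6 s frame interval)."""
    return default_schedule()


@pytest.fixture(scope="session")
def fast_schedule():
    """Reduced schedule: 10 frames per period, 180 frames (60 s interval)."""
    return default_schedule(frame_interval_s=60.0)


@pytest.fixture(scope="session")
def geometry():
    return WellGeometry()


def random_track(rng, schedule, p_move=None, well_id="P1-A01"):
    """A structureless random track used for oracle-equivalence tests."""
    n = schedule.total_frames
    p = p_move if p_move is not None else rng.uniform(0.02, 0.8)
    moved = rng.random(n) < p
    moved[0] = False
    y = np.zeros(n)
    x = np.zeros(n)
    pos = rng.uniform(-1.5, 1.5, size=2)
    for t in range(n):
        if moved[t]:
            pos = rng.uniform(-1.5, 1.5, size=2)
        x[t], y[t] = pos
    return LarvaTrack(well_id=well_id, moved=moved, x_mm=x, y_mm=y)
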