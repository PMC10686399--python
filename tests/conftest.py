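import numpy as np
import pytest

from stare import GazeTrace, OcclusionSchedule, Segment, build_schedule


def make_trace(t, x_left=None, x_right=None, rate=120.0, duration=None,
               valid=None):
    """Build a GazeTrace from arrays, defaulting missing channels to zeros."""
    t = np.asarray(t, dtype=float)
    zeros = np.zeros_like(t)
    ones = np.ones(t.size, dtype=bool)
    v = ones if valid is None else np.asarray(valid, dtype=bool)
    return GazeTrace(
        t=t,
        x_left=zeros if x_left is None else np.asarray(x_left, float),
        x_right=zeros if x_right is None else np.asarray(x_right, float),
        valid_left=v.copy(), valid_right=v.copy(),
        nominal_rate=rate, duration=duration,
    )


def square_wave_trace(height, period=2.0, duration=60.0, rate=120.0,
                      low=0.0):
    """Both eyes follow an ideal square wave between `low` and `low+height`."""
    t = np.arange(int(round(rate * duration))) / rate
    x = np.where((t % period) < period / 2.0, low + height, low)
    return make_trace(t, x_left=x, x_right=x, rate=rate, duration=duration)


@pytest.fixture
def schedule_60s():
    return build_schedule(60.0, 1.0)


@pytest.fixture
def two_second_schedule():
    return OcclusionSchedule(
        [Segment(0.0, 1.0, "right"), Segment(1.0, 2.0, "left")])
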