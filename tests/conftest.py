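import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import streampass as sp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_signed_frame(x, y, start="2015-07-01T12:00"):
    """Build a signed observation frame from raw (x, y) arrays.

    Observations are assigned synthetic hours/directions consistent with
    their signs (sign 0 counts as 'up').
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=float)
    hours = pd.date_range(start, periods=len(x), freq="h")
    direction = np.where(x < 0, "down", "up")
    return pd.DataFrame(
        {
            "hour": hours,
            "direction": direction,
            "photo_signed": x.astype(int),
            "video_signed": y,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160614)


@pytest.fixture
def exact_line_sample():
    """Perfectly linear signed sample with slope 2."""
    x = np.array([1, 2, 3, -1, -2, -4])
    return make_signed_frame(x, 2.0 * x)


@pytest.fixture
def segmented_sample(rng):
    """70-hour sample with distinct up/down detection slopes and mild noise."""
    n = 70
    x_up = rng.integers(1, 80, n)
    x_down = -rng.integers(1, 40, n)
    x = np.concatenate([x_up, x_down])
    slopes = np.where(x > 0, 15.2, 18.9)
    y = slopes * x + rng.normal(0, 15.0, x.size)
    return make_signed_frame(x, y)


@pytest.fixture
def small_scenario():
    """Quick-to-simulate run used by tests that need full ground truth."""
    return sp.RunScenario(
        season_days=30,
        pulses=((8, 6000, 1.5), (18, 3000, 2.0)),
        subsample_hours=70,
    )


@pytest.fixture
def default_scenario():
    return sp.RunScenario()
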