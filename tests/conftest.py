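import numpy as np
import pytest

from btbc.motion import MotionSeries
from btbc.simulate import SimulationConfig


def standardized_series(values, fs=25.0, **kw):
    """Helper: z-score an array into a MotionSeries marked standardized."""
    v = np.asarray(values, dtype=float)
    return MotionSeries((v - v.mean()) / v.std(), fs, standardized=True, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_config():
    """Desk-scale simulation: 2-min interactions, 4 dyads."""
    return SimulationConfig(duration=120.0, n_dyads=4, seed=11)


@pytest.fixture
def toy_series_pair(rng):
    """90-s standardized noise pair (small enough for brute-force oracles)."""
    n = int(90 * 25)
    return (
        standardized_series(rng.normal(size=n), role="instructor"),
        standardized_series(rng.normal(size=n), role="learner"),
    )
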