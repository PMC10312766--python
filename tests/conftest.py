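import numpy as np
import pandas as pd
import pytest

from evmap.config import SimulationConfig
from evmap.io import RegionOfInterest


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def square_roi():
    """Four localizations at the quarter points of a 100×100 nm ROI."""
    df = pd.DataFrame(
        {"id": [0, 1, 2, 3], "frame": 0,
         "x": [25.0, 75.0, 25.0, 75.0], "y": [25.0, 25.0, 75.0, 75.0]}
    )
    return RegionOfInterest("sq", 100.0, 100.0, df)


@pytest.fixture
def uniform_roi(rng):
    """500 uniform background localizations in a 10×10 μm ROI."""
    n = 500
    df = pd.DataFrame(
        {"id": np.arange(n), "frame": 0,
         "x": rng.uniform(0, 10_000, n), "y": rng.uniform(0, 10_000, n)}
    )
    return RegionOfInterest("bg", 10_000.0, 10_000.0, df)


@pytest.fixture
def small_sim_config():
    return SimulationConfig(n_ev=200, n_roi=2, seed=7)
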