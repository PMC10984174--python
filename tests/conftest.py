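import numpy as np
import pandas as pd
import pytest

from roamkit.config import RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def traj():
    """Build a single-animal trajectory frame from positions and minutes."""

    def make(positions, minutes=None, animal="a",
             t0="2021-06-01 00:00:00"):
        if minutes is None:
            minutes = list(range(len(positions)))
        base = pd.Timestamp(t0)
        return pd.DataFrame({
            "animal_id": animal,
            "t": [base + pd.Timedelta(seconds=round(m * 60))
                  for m in minutes],
            "x": [float(p[0]) for p in positions],
            "y": [float(p[1]) for p in positions],
        })

    return make


@pytest.fixture
def gauss_cloud():
    """Isotropic Gaussian fix cloud for kernel home-range checks."""

    def make(n=10_000, sd=10.0, seed=7):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0.0, sd, (n, 2))
        return pd.DataFrame({
            "animal_id": "a",
            "t": pd.date_range("2021-06-01", periods=n, freq="min"),
            "x": pts[:, 0],
            "y": pts[:, 1],
        })

    return make
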