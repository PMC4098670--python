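import numpy as np
import pandas as pd
import pytest

from airsom import PollutantMatrix, SOMGrid, TrainingSchedule, train


@pytest.fixture
def small_matrix():
    """5 complete days x 3 pollutants with simple values."""
    rng = np.random.default_rng(42)
    return PollutantMatrix(
        dates=pd.date_range("2000-01-01", periods=5, freq="D"),
        values=rng.lognormal(mean=1.0, sigma=0.5, size=(5, 3)),
        columns=["CO", "NO2", "O3"],
    )


@pytest.fixture
def clustered_data():
    """Four tight, well-separated 2-D clusters with known labels."""
    rng = np.random.default_rng(7)
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
    labels = np.repeat(np.arange(4), 30)
    Z = centers[labels] + 0.3 * rng.standard_normal((120, 2))
    return Z, labels


@pytest.fixture
def tiny_model(clustered_data):
    """A trained 2x2 map on the four-cluster fixture."""
    Z, _ = clustered_data
    return train(Z, SOMGrid(2, 2), TrainingSchedule(seed=5, t_total=2000))
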