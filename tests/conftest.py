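import numpy as np
import pandas as pd
import pytest

from coraltol import DailySeries
from coraltol.synthetic import SyntheticTruth, default_cells, generate_sst


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def constant_series():
    """Constant 28 °C over 1985–2012 for one cell."""
    idx = pd.date_range("1985-01-01", "2012-12-31", freq="D")
    return DailySeries("c0", 7.0, 134.5, pd.Series(28.0, index=idx))


@pytest.fixture(scope="session")
def small_sst():
    """Three cells of realistic synthetic SST, 1985–2020 (session-cached)."""
    truth = SyntheticTruth(rho_true=0.0, seed=11)
    cells = default_cells(3)
    return cells, generate_sst(cells, (1985, 2020), truth), truth


def make_series(values, start="2000-01-01", cell_id="c0", lat=7.0, lon=134.5):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(cell_id, lat, lon, pd.Series(np.asarray(values, float), index=idx))
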