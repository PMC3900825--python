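import numpy as np
import pandas as pd
import pytest

from svcpois import SVCPoissonRegressor, SimConfig, bootstrap_se, simulate_calls


def make_table(y, start="2000-08-06", tarp_quit=None, tarp_nrt=None):
    """Raw 4-column table for a run of consecutive days starting at `start`."""
    y = np.asarray(y)
    n = len(y)
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n, freq="D").strftime("%Y-%m-%d"),
            "calls": y,
            "tarp_quit": np.zeros(n) if tarp_quit is None else np.asarray(tarp_quit),
            "tarp_nrt": np.zeros(n) if tarp_nrt is None else np.asarray(tarp_nrt),
        }
    )


@pytest.fixture(scope="session")
def sim360():
    """One default-scenario year of synthetic data with its ground truth."""
    return simulate_calls(SimConfig(), seed=101)


@pytest.fixture(scope="session")
def fit360(sim360):
    series, _ = sim360
    return SVCPoissonRegressor(bandwidth=14.0).fit(series)


@pytest.fixture(scope="session")
def boot200(fit360):
    return bootstrap_se(fit360, B=200, seed=7)
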