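import numpy as np
import pandas as pd
import pytest

from phloemetrics.ripening import FitOptions
from phloemetrics.synthetic import SyntheticConfig, generate_weather
from phloemetrics.thermal_time import cumulative_gdd


@pytest.fixture(scope="session")
def config():
    """Default study-condition config with a fixed seed."""
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def gdd_series(config):
    return cumulative_gdd(generate_weather(config), config.gdd_start)


@pytest.fixture
def fit_options():
    return FitOptions(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def constant_weather():
    """30 identical days at (30, 20) °C from July 1."""
    dates = pd.date_range("2020-07-01", periods=30, freq="D")
    return pd.DataFrame({"date": dates, "tmax_c": 30.0, "tmin_c": 20.0})
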