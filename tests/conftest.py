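import numpy as np
import pandas as pd
import pytest

from gravidnet import (
    ClimateParams,
    ScalerParams,
    WeatherSeries,
    generate_weather,
    make_benchmark,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weather(rng, n_days: int = 120, location_id: str = "testloc",
                   start: str = "2016-01-01") -> WeatherSeries:
    """Plain random (non-climatological) weather series for plumbing tests."""
    tmax = 20 + 10 * rng.random(n_days)
    return WeatherSeries(
        location_id=location_id,
        dates=pd.date_range(start, periods=n_days, freq="D"),
        tmax=tmax,
        tmin=tmax - 5 - 5 * rng.random(n_days),
        precip=rng.gamma(0.7, 5.0, n_days) * (rng.random(n_days) < 0.3),
        rh=100 * rng.random(n_days),
    )


@pytest.fixture
def weather_series(rng):
    return random_weather(rng)


@pytest.fixture
def simple_scaler():
    return ScalerParams(minimum=np.array([0.0, 0.0, -10.0, 0.0]),
                        maximum=np.array([50.0, 50.0, 40.0, 100.0]))


@pytest.fixture(scope="session")
def small_benchmark():
    """Six locations (two per climate regime), three years. Shared across
    tests that only read from it."""
    return make_benchmark(n_locations=6, years=3, seed=7)
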