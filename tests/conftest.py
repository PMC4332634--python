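import numpy as np
import pandas as pd
import pytest

from fireniche.synthetic import WeatherGenConfig, default_site, generate_weather
from fireniche.weather_io import SiteParams, WeatherSeries


@pytest.fixture(scope="session")
def site() -> SiteParams:
    return default_site()


@pytest.fixture(scope="session")
def two_year_series() -> WeatherSeries:
    """A 2-year synthetic daily series for index cross-checks."""
    return generate_weather(WeatherGenConfig(years=2, start_year=2001), seed=42)


@pytest.fixture(scope="session")
def four_year_series() -> WeatherSeries:
    return generate_weather(WeatherGenConfig(years=4, start_year=2001), seed=7)


def make_series(frame: pd.DataFrame, site: SiteParams | None = None) -> WeatherSeries:
    return WeatherSeries(frame, site=site)


@pytest.fixture
def small_frame() -> pd.DataFrame:
    """Ten hand-written days, no rain except day 4."""
    dates = pd.date_range("2005-06-01", periods=10, freq="D", name="date")
    return pd.DataFrame(
        {
            "t": [18.0, 20.0, 22.0, 21.0, 17.0, 19.0, 23.0, 25.0, 24.0, 22.0],
            "tmax": [23.0, 26.0, 28.0, 26.0, 20.0, 24.0, 29.0, 31.0, 30.0, 27.0],
            "tmin": [13.0, 14.0, 16.0, 16.0, 14.0, 14.0, 17.0, 19.0, 18.0, 17.0],
            "h": [60.0, 55.0, 50.0, 65.0, 90.0, 70.0, 55.0, 45.0, 50.0, 60.0],
            "p": [0.0, 0.0, 0.0, 0.0, 12.5, 0.0, 0.0, 0.0, 0.0, 0.0],
            "u": [2.0, 3.0, 2.5, 2.0, 4.0, 2.0, 1.5, 3.5, 2.0, 2.5],
            "cloud": [0.2, 0.3, 0.1, 0.5, 0.9, 0.4, 0.2, 0.1, 0.2, 0.3],
            "snow": [0.0] * 10,
        },
        index=dates,
    )
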