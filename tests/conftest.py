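import numpy as np
import pandas as pd
import pytest

from fynhyd import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_weather():
    """30-day dry-season weather, reused across read-only tests."""
    return sd.generate_weather(
        sd.WeatherConfig(season_length_days=30, summer_rain_total=40.0, seed=7)
    )


@pytest.fixture(scope="session")
def dry_season_weather():
    """90-day dry-season scenario (low rain, no large events)."""
    return sd.generate_weather(
        sd.WeatherConfig(season_length_days=90, summer_rain_total=90.0, seed=11)
    )


def meteo_frame(timestamps, **columns):
    """Hand-build a meteo table with given columns and defaults."""
    n = len(timestamps)
    base = {
        "timestamp": pd.DatetimeIndex(timestamps),
        "t_air": np.full(n, 20.0),
        "rh": np.full(n, 60.0),
        "rain": np.zeros(n),
        "wetness_resistance": np.full(n, 10000.0),
        "soil_probe_raw": np.full(n, np.nan),
        "soil_depth": np.full(n, 50.0),
    }
    base.update(columns)
    return pd.DataFrame(base)


@pytest.fixture
def make_meteo():
    return meteo_frame
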