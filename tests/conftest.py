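import numpy as np
import pandas as pd
import pytest

import aedespop as ap


@pytest.fixture(scope="session")
def tokyo():
    return ap.TOKYO_SITE


@pytest.fixture(scope="session")
def params():
    return ap.ModelParams()


@pytest.fixture(scope="session")
def weather3():
    """Three years of seeded synthetic Tokyo-like weather."""
    return ap.generate_weather(ap.WeatherGenConfig(seed=7), 3)


@pytest.fixture(scope="session")
def env3(weather3, tokyo):
    return ap.build_environment(weather3, tokyo)


@pytest.fixture(scope="session")
def traj3(env3, params):
    return ap.simulate(env3, params)


def constant_env(n_days: int, t_air=25.0, t_water=25.0, soil_frac=1.0, w_star=150.0,
                 d_week=12.0, delta_d=0.0) -> pd.DataFrame:
    """A constant environment table (diapause gates off when delta_d = 0)."""
    dates = pd.date_range("2001-01-01", periods=n_days, freq="D")
    return pd.DataFrame(
        {
            "date": dates,
            "photoperiod": d_week,
            "delta_d": delta_d,
            "t_air": t_air,
            "t_water": t_water,
            "soil_water": soil_frac * w_star,
            "w_star": w_star,
            "d_week": d_week,
            "ta_week": t_air,
            "tw_week": t_water,
        }
    )
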