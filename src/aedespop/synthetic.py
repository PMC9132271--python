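"""Seeded synthetic weather and trap-count generation.

The weather generator produces gap-free daily series with the statistical
structure the analysis depends on: a seasonal air-temperature sinusoid with
AR(1) day-to-day noise, precipitation from a two-state (wet/dry) Markov
occurrence chain with gamma-distributed wet-day amounts (zero-inflated and
right-skewed, as real daily rainfall is), and clipped seasonal sinusoids
plus noise for humidity, shortwave radiation, wind and cloud, with cloudier
and more humid wet days.  The defaults emulate Tokyo: annual mean about
16 degC with a 10.5 degC amplitude peaking in early August, and roughly
1400-1600 mm of rain per year.

The trap generator closes the loop: it runs the population model forward
under a known ("truth") parameter set, converts the daily adult series to
weekly expected captures, and draws Poisson counts — giving every
calibration test a data set whose generating parameters are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .environment import Site, build_environment, week_of_year
from .calibration import LAMBDA_FLOOR, expected_weekly_capture
from .population import ModelParams, PopulationState, simulate

TOKYO_SITE = Site(latitude=35.6917, longitude=139.75, altitude=25.0, w_star=150.0)


@dataclass
class WeatherGenConfig:
    """Knobs of the synthetic weather generator (Tokyo-like defaults)."""

    mean_temp: float = 16.0
    temp_amplitude: float = 10.5
    temp_peak_doy: int = 220
    ar1_coeff: float = 0.7
    ar1_sd: float = 1.5
    p_wet_after_dry: float = 0.25
    p_wet_after_wet: float = 0.55
    gamma_shape: float = 0.8
    gamma_scale_mm: float = 14.0
    humidity_mean: float = 65.0
    humidity_amplitude: float = 10.0
    humidity_sd: float = 5.0
    solar_mean: float = 14.0
    solar_amplitude: float = 6.0
    solar_sd: float = 2.0
    wind_mean: float = 3.0
    wind_sd: float = 1.0
    cloud_dry: float = 0.35
    cloud_wet: float = 0.85
    cloud_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_wet_after_dry, self.p_wet_after_wet):
            if not 0 <= p <= 1:
                raise ValueError("Markov probabilities must lie in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_scale_mm <= 0:
            raise ValueError("gamma parameters must be positive")
        for sd in (self.ar1_sd, self.humidity_sd, self.solar_sd, self.wind_sd, self.cloud_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be nonnegative")


def default_truth_params() -> ModelParams:
    """Generating-truth parameter set for the synthetic Tokyo world.

    Identical to the package defaults except that the diapause-termination
    temperature threshold beta_t2 is set to the synthetic world's own
    average week-10 water temperature (about 7 degC), so that the spring
    photoperiod and water-temperature cues cross their thresholds in the
    same week — the phenological coincidence observed at Tokyo, where the
    fitted termination threshold equals the local early-March water
    temperature.  Without it the later-binding cue would mask the other.
    """
    from dataclasses import replace

    base = ModelParams()
    return replace(base, diapause=replace(base.diapause, beta_t2=7.0))


@dataclass
class TrapGenConfig:
    """Truth parameters and observation design for synthetic trap counts."""

    true_params: ModelParams = field(default_factory=default_truth_params)
    burn_in_years: int = 1
    observation_weeks: tuple[int, int] = (1, 52)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.true_params.capture_rate <= 1:
            raise ValueError("capture_rate must be in (0, 1]")


def generate_weather(
    config: WeatherGenConfig, n_years: int, site: Site = TOKYO_SITE, start_year: int = 2001
) -> pd.DataFrame:
    """Generate ``n_years`` of daily synthetic weather starting Jan 1.

    Deterministic given ``config.seed``; the output passes
    :func:`aedespop.environment.validate_weather`.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    phase = 2 * np.pi * (doy - config.temp_peak_doy) / 365.25

    t_season = config.mean_temp + config.temp_amplitude * np.cos(phase)
    noise = np.zeros(n)
    eps = rng.normal(0.0, config.ar1_sd, size=n)
    for i in range(1, n):
        noise[i] = config.ar1_coeff * noise[i - 1] + eps[i]
    t_air = t_season + noise

    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < config.p_wet_after_dry
    for i in range(1, n):
        p = config.p_wet_after_wet if wet[i - 1] else config.p_wet_after_dry
        wet[i] = u[i] < p
    precip = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        precip[wet] = rng.gamma(config.gamma_shape, config.gamma_scale_mm, size=n_wet)

    rh = np.clip(
        config.humidity_mean
        + config.humidity_amplitude * np.cos(phase)
        + 10.0 * wet
        + rng.normal(0.0, config.humidity_sd, size=n),
        5.0,
        100.0,
    )
    solar = np.clip(
        config.solar_mean
        + config.solar_amplitude * np.cos(2 * np.pi * (doy - 172) / 365.25)
        - 6.0 * wet
        + rng.normal(0.0, config.solar_sd, size=n),
        0.5,
        None,
    )
    wind = np.clip(rng.normal(config.wind_mean, config.wind_sd, size=n), 0.1, None)
    cloud = np.clip(
        np.where(wet, config.cloud_wet, config.cloud_dry) + rng.normal(0.0, config.cloud_sd, size=n),
        0.0,
        1.0,
    )
    return pd.DataFrame(
        {
            "date": dates,
            "t_air": t_air,
            "precip": precip,
            "rel_humidity": rh,
            "solar_rad": solar,
            "wind": wind,
            "cloud": cloud,
        }
    )


def stationary_wet_probability(config: WeatherGenConfig) -> float:
    """Stationary wet-day probability p01 / (1 + p01 - p11) of the chain."""
    p01, p11 = config.p_wet_after_dry, config.p_wet_after_wet
    return p01 / (1.0 + p01 - p11)


def generate_trap_counts(
    weather: pd.DataFrame,
    config: TrapGenConfig,
    site: Site = TOKYO_SITE,
    habitat_config=None,
) -> tuple[pd.DataFrame, dict]:
    """Forward-simulate with the truth parameters and draw Poisson counts.

    Weeks in ``config.observation_weeks`` of every post-burn-in complete
    year are observed.  Returns ``(observations, truth)`` where truth holds
    the generating parameters and the noiseless expected-capture series.
    """
    if config.true_params.capture_rate <= 0:
        raise ValueError("capture_rate must be positive")
    env = build_environment(weather, site, habitat_config)
    traj = simulate(env, config.true_params)
    dates = pd.DatetimeIndex(traj["date"])
    years = sorted(set(dates.year))
    counts_per_year = pd.Series(dates.year).value_counts()
    obs_years = [y for y in years if counts_per_year[y] >= 365][config.burn_in_years:]
    lo, hi = config.observation_weeks
    years_all = np.asarray(dates.year)
    weeks_all = week_of_year(dates)
    rows = []
    for year in obs_years:
        for week in range(lo, hi + 1):
            mask = (years_all == year) & (weeks_all == week)
            first = dates[mask][0]
            rows.append({"date": first, "year": int(year), "week": int(week)})
    obs = pd.DataFrame(rows)
    lam = expected_weekly_capture(traj, obs, config.true_params.capture_rate)
    rng = np.random.default_rng(config.seed)
    obs["count"] = rng.poisson(lam)
    truth = {
        "params": config.true_params,
        "lambda": lam,
        "trajectory": traj,
        "seed": config.seed,
    }
    return obs, truth


def make_fixture_bundle(seed: int, out_dir) -> dict:
    """Write the canonical small fixture: 3-year weather, 2 observed years.

    Produces ``weather.csv``, ``traps.csv`` and ``truth.yaml`` (generating
    parameters and scalar metadata) in ``out_dir`` and returns the paths
    plus the in-memory truth record.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wcfg = WeatherGenConfig(seed=seed)
    weather = generate_weather(wcfg, n_years=3)
    tcfg = TrapGenConfig(seed=seed + 1)
    obs, truth = generate_trap_counts(weather, tcfg)
    weather_path = out_dir / "weather.csv"
    traps_path = out_dir / "traps.csv"
    truth_path = out_dir / "truth.yaml"
    weather.assign(date=weather["date"].dt.strftime("%Y-%m-%d")).to_csv(weather_path, index=False)
    obs[["date", "count"]].assign(date=obs["date"].dt.strftime("%Y-%m-%d")).to_csv(
        traps_path, index=False
    )
    with open(truth_path, "w") as fh:
        yaml.safe_dump(
            {
                "seed": seed,
                "weather_config": asdict(wcfg),
                "site": asdict(TOKYO_SITE),
                "true_params": tcfg.true_params.to_dict(),
                "burn_in_years": tcfg.burn_in_years,
            },
            fh,
        )
    return {
        "weather": weather_path,
        "traps": traps_path,
        "truth_config": truth_path,
        "truth": truth,
    }
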