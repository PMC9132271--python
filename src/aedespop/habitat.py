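"""Aquatic-habitat drivers: container water temperature and soil water.

Two small sub-models sit between raw weather and the population dynamics:

* ``water_temperature`` — daily mean temperature of a small open water
  container.  Each day an equilibrium temperature is computed from a
  linearised surface energy balance (absorbed shortwave, cloud- and
  humidity-adjusted net longwave loss, a wind-dependent latent-heat term)
  and the water relaxes toward it at a first-order rate.  Small containers
  track air temperature closely; the equilibrium offset is the net daytime
  energy input divided by a bulk exchange conductance.

* ``soil_water_balance`` — a single-bucket soil water model with a snow
  store.  Precipitation falls as snow below a partition temperature, snow
  melts at a degree-day rate, and water leaves as actual evapotranspiration
  (potential evapotranspiration scaled by the bucket fill W/W*) or as
  overflow once the bucket is full.  Potential evapotranspiration uses the
  Thornthwaite temperature method with the monthly total distributed over
  days in proportion to daylength.

Both sub-models are deliberately narrow interfaces: the population module
only ever sees the daily water temperature and the soil-moisture ratio
W/W*, so either sub-model can be replaced without touching it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import Site, photoperiod_series


@dataclass(frozen=True)
class HabitatConfig:
    """Parameters of the habitat sub-models (all rates nonnegative).

    Attributes
    ----------
    relax_rate : float
        Fraction of the gap to the equilibrium temperature closed per day
        (1/day, in (0, 1]); 0.6 suits containers of a few litres.
    albedo : float
        Shortwave reflectivity of the water surface.
    exchange_base, exchange_wind : float
        Bulk heat-exchange conductance, MJ m-2 day-1 K-1:
        ``h = exchange_base + exchange_wind * wind``.
    longwave_coeff : float
        Scale of the net longwave loss, MJ m-2 day-1 (order sigma*T^4).
    latent_coeff, latent_wind : float
        Latent-heat loss = ``latent_coeff * (1 + latent_wind*wind) * VPD``
        with the vapour-pressure deficit in kPa.
    snow_temp : float
        Air temperature (degC) below which precipitation falls as snow.
    melt_coeff : float
        Degree-day snowmelt coefficient, mm per degC per day.
    initial_soil_fraction : float
        Bucket fill W/W* on the first simulated day (wet-winter start).
    """

    relax_rate: float = 0.6
    albedo: float = 0.07
    exchange_base: float = 10.0
    exchange_wind: float = 2.0
    longwave_coeff: float = 35.0
    latent_coeff: float = 3.0
    latent_wind: float = 0.5
    snow_temp: float = 0.0
    melt_coeff: float = 3.0
    initial_soil_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("relax_rate", "exchange_base", "exchange_wind", "longwave_coeff",
                     "latent_coeff", "latent_wind", "melt_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.relax_rate <= 1:
            raise ValueError("relax_rate must be in (0, 1]")


def saturation_vapour_pressure(t_air) -> np.ndarray:
    """Tetens saturation vapour pressure over water, kPa."""
    t = np.asarray(t_air, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def equilibrium_water_temperature(weather: pd.DataFrame, config: HabitatConfig) -> np.ndarray:
    """Daily equilibrium temperature of the container (degC).

    Teq = Ta + (S_abs - L_net - LE) / h with
    S_abs = (1 - albedo) * shortwave,
    L_net = longwave_coeff * (0.34 - 0.14 sqrt(e_a)) * (1 - 0.8 cloud),
    LE    = latent_coeff * (1 + latent_wind * wind) * (e_s(Ta) - e_a),
    h     = exchange_base + exchange_wind * wind.

    With zero radiation, saturated air and calm wind the offset reduces to
    -L_net / exchange_base, a few tenths of a degree.
    """
    ta = weather["t_air"].to_numpy(dtype=float)
    es = saturation_vapour_pressure(ta)
    ea = weather["rel_humidity"].to_numpy(dtype=float) / 100.0 * es
    s_abs = (1.0 - config.albedo) * weather["solar_rad"].to_numpy(dtype=float)
    l_net = (
        config.longwave_coeff
        * np.maximum(0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)), 0.0)
        * (1.0 - 0.8 * weather["cloud"].to_numpy(dtype=float))
    )
    wind = weather["wind"].to_numpy(dtype=float)
    latent = config.latent_coeff * (1.0 + config.latent_wind * wind) * (es - ea)
    h = config.exchange_base + config.exchange_wind * wind
    return ta + (s_abs - l_net - latent) / h


def water_temperature(weather: pd.DataFrame, config: HabitatConfig | None = None) -> np.ndarray:
    """Daily mean container water temperature (degC), floored at 0 (ice).

    First-order relaxation toward the daily equilibrium temperature:
    ``Tw(t+1) = Tw(t) + relax_rate * (Teq(t+1) - Tw(t))``, started at
    ``max(Ta(0), 0)``.
    """
    if config is None:
        config = HabitatConfig()
    teq = equilibrium_water_temperature(weather, config)
    tw = np.empty_like(teq)
    tw[0] = max(float(weather["t_air"].iloc[0]), 0.0)
    r = config.relax_rate
    for i in range(1, len(teq)):
        tw[i] = tw[i - 1] + r * (teq[i] - tw[i - 1])
    return np.maximum(tw, 0.0)


def potential_evapotranspiration(
    weather: pd.DataFrame, site: Site
) -> np.ndarray:
    """Daily potential evapotranspiration (mm) by the Thornthwaite method.

    Monthly PET = 16 (L/12) (N/30) (10 T_m / I)^a, where T_m is the monthly
    mean air temperature (months averaged over all years present), I the
    annual heat index and L the mean daylength of the month.  The monthly
    total is distributed over the days of the month in proportion to each
    day's daylength, and days with Ta <= 0 degC receive zero.
    """
    dates = pd.DatetimeIndex(weather["date"])
    ta = weather["t_air"].to_numpy(dtype=float)
    month = dates.month.to_numpy()
    # monthly climatological means over the whole series
    t_month = np.array([ta[month == m].mean() if (month == m).any() else 0.0 for m in range(1, 13)])
    t_pos = np.maximum(t_month, 0.0)
    heat_index = float(np.sum((t_pos / 5.0) ** 1.514))
    if heat_index <= 0:
        return np.zeros(len(ta))
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    daylength = photoperiod_series(site, dates)
    pet = np.zeros(len(ta))
    for (year, m), idx in pd.Series(range(len(dates)), index=dates).groupby(
        [dates.year, dates.month]
    ):
        pos = idx.to_numpy()
        n_days = len(pos)
        l_mean = daylength[pos].mean()
        pet_month = 16.0 * (l_mean / 12.0) * (n_days / 30.0) * (10.0 * t_pos[m - 1] / heat_index) ** a
        weights = daylength[pos]
        total_w = weights.sum()
        if total_w > 0:
            pet[pos] = pet_month * weights / total_w
        else:
            pet[pos] = pet_month / n_days
    pet[ta <= 0.0] = 0.0
    return np.maximum(pet, 0.0)


def soil_water_balance(
    weather: pd.DataFrame,
    site: Site,
    config: HabitatConfig | None = None,
    initial_soil_water: float | None = None,
    initial_snowpack: float = 0.0,
    pet: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the daily bucket model and return the full water ledger.

    Update per day: partition precipitation into rain/snow at
    ``config.snow_temp``; melt = min(snowpack, melt_coeff * max(Ta, 0));
    AET = PET * W/W* (unscaled when the bucket is full), capped by the
    water available; W(t+1) = clamp(W(t) + rain + melt - AET, 0, W*), the
    excess leaving as overflow.

    Returns a DataFrame with columns ``date, soil_water, snowpack, rain,
    snowfall, melt, aet, overflow``; the mass balance
    ``sum(precip) - sum(aet) - sum(overflow) = dW + d(snowpack)``
    closes to rounding error by construction.
    """
    if config is None:
        config = HabitatConfig()
    if pet is None:
        pet = potential_evapotranspiration(weather, site)
    precip = weather["precip"].to_numpy(dtype=float)
    ta = weather["t_air"].to_numpy(dtype=float)
    n = len(precip)
    w_star = site.w_star
    w = w_star * config.initial_soil_fraction if initial_soil_water is None else initial_soil_water
    snow = initial_snowpack

    cols = {k: np.zeros(n) for k in ("soil_water", "snowpack", "rain", "snowfall", "melt", "aet", "overflow")}
    for i in range(n):
        is_snow = ta[i] < config.snow_temp
        snowfall = precip[i] if is_snow else 0.0
        rain = precip[i] - snowfall
        snow += snowfall
        melt = min(snow, config.melt_coeff * max(ta[i], 0.0))
        snow -= melt
        fill = w / w_star
        aet = pet[i] * (1.0 if fill >= 1.0 else fill)
        avail = w + rain + melt
        aet = min(aet, avail)
        w_new = avail - aet
        overflow = max(w_new - w_star, 0.0)
        w = w_new - overflow
        cols["soil_water"][i] = w
        cols["snowpack"][i] = snow
        cols["rain"][i] = rain
        cols["snowfall"][i] = snowfall
        cols["melt"][i] = melt
        cols["aet"][i] = aet
        cols["overflow"][i] = overflow
    out = pd.DataFrame(cols)
    out.insert(0, "date", pd.DatetimeIndex(weather["date"]))
    return out
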