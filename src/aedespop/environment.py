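"""Daily weather ingestion and the astronomical / climatological drivers.

This module turns a raw daily weather series into the environmental cues the
population model consumes: astronomical photoperiod ``D`` (daylength in
hours), its day-to-day change ``dD``, and trailing 7-day means of
photoperiod, air temperature and water temperature.  Photoperiod follows the
standard solar-position calculation (Spencer Fourier declination, sunrise
hour angle at a zenith of 90.833 deg so that atmospheric refraction and the
solar disc radius are included).

Weather files are plain CSV with one row per day and columns
``date,t_air,precip,rel_humidity,solar_rad,wind,cloud``; trap-count files
are CSV with ``date,count``.  Units: temperature degC, precipitation mm/day,
relative humidity %, shortwave radiation MJ m-2 day-1, wind m/s, cloud
amount as a 0-1 fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientSeriesError,
    InvalidSiteError,
    WeatherFormatError,
)

WEATHER_COLUMNS = ["date", "t_air", "precip", "rel_humidity", "solar_rad", "wind", "cloud"]

#: Solar zenith angle (degrees) defining sunrise/sunset; 90.833 deg accounts
#: for refraction plus the apparent solar radius.
SUNRISE_ZENITH_DEG = 90.833


@dataclass(frozen=True)
class Site:
    """Location and soil description of the study site.

    Parameters
    ----------
    latitude, longitude : float
        Decimal degrees; latitude must lie in [-90, 90].
    altitude : float
        Metres above sea level (informational; not used in the daylength
        calculation).
    w_star : float
        Soil water-holding capacity W* in mm; the ceiling of the soil
        water bucket and the denominator of the soil-moisture ratio W/W*.
    """

    latitude: float
    longitude: float = 0.0
    altitude: float = 0.0
    w_star: float = 150.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise InvalidSiteError(f"latitude {self.latitude} outside [-90, 90]")
        if not self.w_star > 0:
            raise InvalidSiteError(f"w_star must be positive, got {self.w_star}")


def _days_in_year(year: int) -> int:
    return 366 if (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)) else 365


def solar_declination(day_of_year, year: int = 2005):
    """Solar declination (radians) from the Spencer Fourier series."""
    g = 2.0 * np.pi / _days_in_year(year) * (np.asarray(day_of_year, dtype=float) - 1.0)
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def photoperiod(site: Site, day_of_year, year: int = 2005):
    """Sunrise-to-sunset daylength in hours.

    Uses the sunrise hour angle at a solar zenith of 90.833 deg.  Returns
    24 during polar day and 0 during polar night (no horizon crossing).
    Accepts a scalar or an array of day-of-year values.

    Parameters
    ----------
    site : Site
    day_of_year : int or array of int
        1-based day of year (1..365/366).
    year : int
        Calendar year, used only for the length of the year.
    """
    doy = np.asarray(day_of_year)
    if np.any(doy < 1) or np.any(doy > _days_in_year(year)):
        raise ValueError(f"day_of_year outside 1..{_days_in_year(year)}")
    decl = solar_declination(doy, year)
    lat = np.deg2rad(site.latitude)
    cos_ha = np.cos(np.deg2rad(SUNRISE_ZENITH_DEG)) / (np.cos(lat) * np.cos(decl)) - np.tan(
        lat
    ) * np.tan(decl)
    # |cos_ha| > 1 means the sun never crosses the horizon that day.
    cos_ha = np.clip(cos_ha, -1.0, 1.0)
    daylength = 2.0 * np.rad2deg(np.arccos(cos_ha)) / 15.0
    if np.isscalar(day_of_year):
        return float(daylength)
    return daylength


def photoperiod_series(site: Site, dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Daylength for every date in a (gap-free) daily date vector."""
    dates = pd.DatetimeIndex(dates)
    out = np.empty(len(dates))
    for year, idx in dates.groupby(dates.year).items():
        pos = dates.get_indexer(idx)
        out[pos] = photoperiod(site, idx.dayofyear.to_numpy(), int(year))
    return out


def delta_photoperiod(daylengths) -> np.ndarray:
    """Day-to-day change dD(t) = D(t) - D(t-1) in hours per day.

    The first element copies the second so the diapause gates, which switch
    on the sign of dD, never see an undefined value.
    """
    d = np.asarray(daylengths, dtype=float)
    if d.size < 2:
        raise InsufficientSeriesError("delta_photoperiod needs at least 2 days")
    dd = np.empty_like(d)
    dd[1:] = np.diff(d)
    dd[0] = dd[1]
    return dd


def rolling_week_mean(values) -> np.ndarray:
    """Trailing 7-day mean including the current day.

    The first six elements average whatever history exists (1..6 days).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientSeriesError("rolling_week_mean needs a non-empty series")
    return pd.Series(v).rolling(7, min_periods=1).mean().to_numpy()


def _check_gapfree(dates: pd.Series, what: str) -> None:
    dup = dates[dates.duplicated()]
    if len(dup):
        raise WeatherFormatError(f"duplicate dates in {what}: {list(dup.dt.date)}")
    if len(dates) > 1:
        full = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
        missing = full.difference(pd.DatetimeIndex(dates))
        if len(missing):
            shown = ", ".join(str(d.date()) for d in missing[:5])
            more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
            raise WeatherFormatError(f"date gaps in {what}: {shown}{more}")
        if not dates.is_monotonic_increasing:
            raise WeatherFormatError(f"dates in {what} are not increasing")


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a weather frame against the daily-weather invariants.

    Raises :class:`WeatherFormatError` naming the first offending rows.
    Returns the frame with ``date`` parsed to datetime.
    """
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherFormatError(f"missing weather columns: {missing}")
    df = df.copy()
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise WeatherFormatError(f"unparsable date: {exc}") from exc
    checks = [
        ("precip", df["precip"] < 0, "negative precipitation"),
        ("rel_humidity", ~df["rel_humidity"].between(0, 100), "humidity outside 0-100"),
        ("cloud", ~df["cloud"].between(0, 1), "cloud outside 0-1"),
        ("wind", df["wind"] < 0, "negative wind speed"),
        ("t_air", ~np.isfinite(df["t_air"]), "non-finite air temperature"),
    ]
    for col, bad, msg in checks:
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise WeatherFormatError(f"{msg} in column {col!r} at file row(s) {rows}")
    _check_gapfree(df["date"], "weather series")
    return df.reset_index(drop=True)


def read_weather(path) -> pd.DataFrame:
    """Read and validate a daily weather CSV.

    Returns a DataFrame with columns ``date`` (datetime) plus the six
    meteorological variables, one row per day, gap-free.  Floats are
    parsed round-trip-exactly so a written series re-simulates
    bit-for-bit.
    """
    return validate_weather(pd.read_csv(path, float_precision="round_trip"))


def read_traps(path) -> pd.DataFrame:
    """Read a weekly trap-count CSV (columns ``date,count``).

    Each observation is assigned to the 7-day block of its collection date,
    counted from January 1 (week 1 = days 1-7).  Returns a DataFrame with
    ``date, count, year, week``.
    """
    df = pd.read_csv(path)
    for col in ("date", "count"):
        if col not in df.columns:
            raise WeatherFormatError(f"missing trap column {col!r}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise WeatherFormatError(f"unparsable date: {exc}") from exc
    bad = (df["count"] < 0) | (df["count"] != df["count"].astype(int))
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise WeatherFormatError(f"counts must be nonnegative integers; file row(s) {rows}")
    df["count"] = df["count"].astype(int)
    df["year"] = df["date"].dt.year
    df["week"] = week_of_year(df["date"])
    if df.duplicated(["year", "week"]).any():
        raise WeatherFormatError("multiple observations fall in the same year/week block")
    return df


def week_of_year(dates) -> np.ndarray:
    """1-based 7-day block index from January 1 (week w = days 7(w-1)+1..7w)."""
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    return (doy - 1) // 7 + 1


def build_environment(weather: pd.DataFrame, site: Site, habitat_config=None) -> pd.DataFrame:
    """Assemble the daily environment table driving the population model.

    Combines photoperiod (``photoperiod``), its daily change, the habitat
    sub-models (water temperature and soil water, see :mod:`aedespop.habitat`)
    and the trailing 7-day means used by the diapause gates.

    Returns a DataFrame with columns ``date, photoperiod, delta_d, t_air,
    t_water, soil_water, w_star, d_week, ta_week, tw_week``.
    """
    from .habitat import HabitatConfig, soil_water_balance, water_temperature

    weather = validate_weather(weather)
    if habitat_config is None:
        habitat_config = HabitatConfig()
    daylength = photoperiod_series(site, weather["date"])
    t_water = water_temperature(weather, habitat_config)
    soil = soil_water_balance(weather, site, habitat_config)
    env = pd.DataFrame(
        {
            "date": weather["date"],
            "photoperiod": daylength,
            "delta_d": delta_photoperiod(daylength),
            "t_air": weather["t_air"].to_numpy(dtype=float),
            "t_water": t_water,
            "soil_water": soil["soil_water"].to_numpy(),
            "w_star": site.w_star,
            "d_week": rolling_week_mean(daylength),
            "ta_week": rolling_week_mean(weather["t_air"].to_numpy()),
            "tw_week": rolling_week_mean(t_water),
        }
    )
    return env
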