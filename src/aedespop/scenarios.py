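"""Scenario runs, seasonal summaries and model/climate comparisons.

Given a simulated trajectory, :func:`summarize` reduces it to weekly mean
adult abundance per year, averages the weekly series across years, and
extracts the seasonal descriptors used for scenario comparison: peak of the
averaged dynamics, the week it occurs, and the onset/termination weeks of
the active season (first/last week at or above a threshold fraction of the
peak, 5 % by default).

:func:`compare_models` is the peak ratio between two summaries (e.g. the
rainfall-responsive vs fixed-capacity model under the same warming
scenario); :func:`compute_bias` is the same ratio between two climate
inputs for one model, used to correct raw ratios for climate-input bias.
:func:`scenario_shift` applies a uniform warming offset and a wet-day
precipitation scaling to a weather series to emulate emission-scenario
forcing without any climate-model data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import week_of_year


@dataclass
class ScenarioSummary:
    """Weekly adult dynamics of one scenario run.

    Attributes
    ----------
    weekly : DataFrame
        Columns ``year, week, adults`` (weekly mean adult abundance).
    averaged : DataFrame
        Columns ``week, adults`` — the cross-year average by week.
    peak : float
        Maximum of the averaged weekly series.
    peak_week : int
        Week of the maximum (earliest on ties).
    onset_week, termination_week : int
        First and last week with averaged adults >= threshold * peak.
    threshold : float
        The onset/termination threshold fraction.
    """

    weekly: pd.DataFrame
    averaged: pd.DataFrame
    peak: float
    peak_week: int
    onset_week: int
    termination_week: int
    threshold: float


def weekly_mean_adults(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Weekly (7-day block) mean adult abundance, one row per year-week."""
    dates = pd.DatetimeIndex(trajectory["date"])
    df = pd.DataFrame(
        {"year": dates.year, "week": week_of_year(dates), "adults": trajectory["A"].to_numpy()}
    )
    return df.groupby(["year", "week"], as_index=False)["adults"].mean()


def summarize(
    trajectory: pd.DataFrame,
    burn_in_years: int = 0,
    threshold: float = 0.05,
    drop_incomplete_years: bool = True,
) -> ScenarioSummary:
    """Summarize a daily trajectory into averaged weekly dynamics.

    Years with fewer than 365 days are excluded (with a warning) unless
    ``drop_incomplete_years`` is False; the first ``burn_in_years``
    complete years are discarded before averaging.
    """
    dates = pd.DatetimeIndex(trajectory["date"])
    counts = pd.Series(dates.year).value_counts()
    years = sorted(counts.index)
    if drop_incomplete_years:
        kept = [y for y in years if counts[y] >= 365]
        dropped = set(years) - set(kept)
        if dropped:
            import warnings

            warnings.warn(f"excluding incomplete year(s) {sorted(dropped)}", stacklevel=2)
        years = kept
    years = years[burn_in_years:]
    if not years:
        raise ValueError("no complete year left after burn-in")
    mask = np.isin(dates.year, years)
    weekly = weekly_mean_adults(trajectory[mask]).reset_index(drop=True)
    averaged = weekly.groupby("week", as_index=False)["adults"].mean()
    peak = float(averaged["adults"].max())
    peak_week = int(averaged.loc[averaged["adults"].idxmax(), "week"])  # idxmax: earliest tie
    active = averaged[averaged["adults"] >= threshold * peak] if peak > 0 else averaged
    onset = int(active["week"].min())
    term = int(active["week"].max())
    return ScenarioSummary(
        weekly=weekly,
        averaged=averaged,
        peak=peak,
        peak_week=peak_week,
        onset_week=onset,
        termination_week=term,
        threshold=threshold,
    )


def _peak(obj) -> float:
    return float(obj.peak) if hasattr(obj, "peak") else float(obj)


def compare_models(summary_a, summary_b) -> float:
    """Peak ratio peak(a)/peak(b), rounded to 2 decimals.

    Accepts :class:`ScenarioSummary` objects or bare peak values.
    """
    pb = _peak(summary_b)
    if pb == 0:
        raise ZeroDivisionError("denominator summary has zero peak")
    return round(_peak(summary_a) / pb, 2)


def compute_bias(summary_model_climate, summary_obs_climate) -> float:
    """Climate-input bias: peak under modelled climate / peak under
    observed climate, same population parameters.  A raw cross-model ratio
    is bias-corrected by dividing by this factor."""
    pb = _peak(summary_obs_climate)
    if pb == 0:
        raise ZeroDivisionError("observation-driven summary has zero peak")
    return _peak(summary_model_climate) / pb


def driver_histogram(series, variable: str, bin_width: float = 5.0) -> pd.DataFrame:
    """Frequency table of a habitat driver.

    For ``variable='precipitation'`` the first bin is a dedicated
    exact-zero bin followed by uniform ``bin_width``-mm bins; for
    ``variable='soil_moisture_ratio'`` the series (in %) is binned on
    0-100 with uniform bins.  Returns ``bin_left, bin_right, count``.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    rows = []
    if variable == "precipitation":
        zero = int(np.sum(x == 0.0))
        rows.append((0.0, 0.0, zero))
        pos = x[x > 0]
        top = float(pos.max()) if pos.size else bin_width
        n_bins = int(np.ceil(top / bin_width)) or 1
        edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
        counts, _ = np.histogram(pos, bins=edges)
        for i, c in enumerate(counts):
            rows.append((edges[i], edges[i + 1], int(c)))
    elif variable == "soil_moisture_ratio":
        edges = np.arange(0.0, 100.0 + bin_width, bin_width)
        counts, _ = np.histogram(np.clip(x, 0, 100), bins=edges)
        # np.histogram puts 100 in the last bin already
        for i, c in enumerate(counts):
            rows.append((edges[i], edges[i + 1], int(c)))
    else:
        raise ValueError(f"unknown variable {variable!r}")
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "count"])


def scenario_shift(
    weather: pd.DataFrame, delta_t: float = 0.0, precip_scale: float = 1.0
) -> pd.DataFrame:
    """Uniform warming + wet-day precipitation scaling of a weather series.

    Air temperature is shifted by ``delta_t`` everywhere; precipitation
    amounts on wet days are multiplied by ``precip_scale`` (dry days stay
    dry); all other variables are untouched.
    """
    if not np.isfinite(delta_t):
        raise ValueError("delta_t must be finite")
    if precip_scale < 0:
        raise ValueError("precip_scale must be nonnegative")
    out = weather.copy()
    out["t_air"] = out["t_air"] + delta_t
    out["precip"] = out["precip"] * precip_scale
    return out
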