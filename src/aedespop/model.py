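"""Model / Results front end tying the pieces together.

:class:`MosquitoPopulationModel` is constructed from data (daily weather,
weekly trap counts, site metadata); ``fit()`` runs the annealing
calibration and returns a :class:`MosquitoPopulationResults` carrying the
estimates, likelihood diagnostics and a ``summary()`` table, with
``predict()`` / ``simulate()`` for expected weekly captures and full stage
trajectories.  This mirrors the model/results split of statsmodels: the
model owns the data and the likelihood, the results object owns a fitted
parameter set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationConfig,
    CalibrationResult,
    LikelihoodEvaluator,
    calibrate,
    period_log_likelihood,
)
from .environment import Site, build_environment, read_traps, read_weather
from .population import ModelParams, PopulationState, simulate


class MosquitoPopulationModel:
    """Stage-structured mosquito population model bound to one site's data.

    Parameters
    ----------
    trap_counts : DataFrame
        Weekly counts with columns ``year, week, count`` (or ``date,
        count``; dates are assigned to 7-day blocks from Jan 1).
    weather : DataFrame
        Daily weather covering the observations plus the burn-in.
    site : Site
    params : ModelParams, optional
        Starting/base parameter set; thermal curves and capture rate are
        held fixed during fitting.
    habitat_config : HabitatConfig, optional
    burn_in_years : int
        Leading years excluded from the likelihood (population spin-up
        from the overwintering egg stock).
    """

    def __init__(
        self,
        trap_counts: pd.DataFrame,
        weather: pd.DataFrame,
        site: Site,
        params: ModelParams | None = None,
        habitat_config=None,
        burn_in_years: int = 1,
    ):
        self.site = site
        self.base_params = params or ModelParams()
        self.burn_in_years = burn_in_years
        self.weather = weather
        self.env = build_environment(weather, site, habitat_config)
        obs = trap_counts.copy()
        if "week" not in obs.columns or "year" not in obs.columns:
            from .environment import week_of_year

            obs["date"] = pd.to_datetime(obs["date"])
            obs["year"] = obs["date"].dt.year
            obs["week"] = week_of_year(obs["date"])
        self.observations = obs.reset_index(drop=True)
        self._evaluator = LikelihoodEvaluator(self.env, self.observations, self.base_params)

    @classmethod
    def from_csv(
        cls, traps_path, weather_path, site: Site, **kwargs
    ) -> "MosquitoPopulationModel":
        """Build the model from the weather and trap-count CSV dialects."""
        return cls(read_traps(traps_path), read_weather(weather_path), site, **kwargs)

    @property
    def nobs(self) -> int:
        return len(self.observations)

    def loglike(self, params: ModelParams | None = None) -> float:
        """Poisson log-likelihood of the counts under ``params``."""
        return self._evaluator.loglik(params or self.base_params)

    def simulate(
        self, params: ModelParams | None = None, initial_state: PopulationState | None = None
    ) -> pd.DataFrame:
        """Daily stage trajectory under ``params`` (burn-in included)."""
        return simulate(self.env, params or self.base_params, initial_state)

    def fit(
        self, config: CalibrationConfig | None = None, seed: int | None = None
    ) -> "MosquitoPopulationResults":
        """Run the simulated-annealing calibration.

        ``seed`` overrides ``config.seed`` when given.  Returns a results
        object wrapping the best parameter set found.
        """
        config = config or CalibrationConfig()
        if seed is not None:
            config = CalibrationConfig(
                param_space=config.param_space,
                initial_temp=config.initial_temp,
                cooling=config.cooling,
                iters_per_level=config.iters_per_level,
                n_levels=config.n_levels,
                seed=seed,
                burn_in_years=config.burn_in_years,
            )
        result = calibrate(self.observations, self.env, self.base_params, config)
        return MosquitoPopulationResults(self, result)


class MosquitoPopulationResults:
    """Fitted parameters plus diagnostics, in the statsmodels idiom."""

    def __init__(self, model: MosquitoPopulationModel, result: CalibrationResult):
        self.model = model
        self._result = result
        self.params: ModelParams = result.params
        self.llf: float = result.log_likelihood
        self.seed = result.seed

    @property
    def loglik_trace(self) -> np.ndarray:
        return self._result.loglik_trace

    @property
    def best_trace(self) -> np.ndarray:
        return self._result.best_trace

    @property
    def acceptance_rate(self) -> np.ndarray:
        return self._result.acceptance_rate

    def predict(self) -> pd.DataFrame:
        """Observed counts alongside fitted expected weekly captures."""
        lam = self.model._evaluator.expected_captures(self.params)
        out = self.model.observations.copy()
        out["expected"] = lam
        return out

    def simulate(self) -> pd.DataFrame:
        """Daily stage trajectory under the fitted parameters."""
        return self.model.simulate(self.params)

    def period_loglik(self, week_ranges=((16, 23), (29, 36), (42, 49))) -> dict:
        """Mean annual log-likelihood restricted to seasonal week ranges."""
        lam = self.model._evaluator.expected_captures(self.params)
        return period_log_likelihood(self.model.observations, lam, list(week_ranges))

    def plot(self, ax=None):
        """Observed weekly counts against the fitted expectation."""
        import matplotlib.pyplot as plt

        pred = self.predict()
        x = pred["year"] + (pred["week"] - 1) / 53.0
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        ax.plot(x, pred["count"], "o", ms=3, color="black", label="observed")
        ax.plot(x, pred["expected"], "-", color="tab:red", label="expected captures")
        ax.set_xlabel("year")
        ax.set_ylabel("weekly captures")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        d = self.params.diapause
        c = self.params.capacity
        rows = [
            ("kappa_max", c.kappa_max, f"10^{np.log10(c.kappa_max):.2f}"),
            ("nu", c.nu, ""),
            ("alpha_d1 (per h)", d.alpha_d1, f"10^{np.log10(d.alpha_d1):.2f}"),
            ("alpha_d2 (per h)", d.alpha_d2, f"10^{np.log10(d.alpha_d2):.2f}"),
            ("alpha_t1 (per degC)", d.alpha_t1, f"10^{np.log10(d.alpha_t1):.2f}"),
            ("alpha_t2 (per degC)", d.alpha_t2, f"10^{np.log10(d.alpha_t2):.2f}"),
            ("beta_d1 (h)", d.beta_d1, ""),
            ("beta_d2 (h)", d.beta_d2, ""),
            ("beta_t1 (degC)", d.beta_t1, ""),
            ("beta_t2 (degC)", d.beta_t2, ""),
        ]
        lines = [
            "Mosquito Population Model — annealing fit",
            "=" * 57,
            f"No. observations: {self.model.nobs:>6d}    Log-likelihood: {self.llf:.3f}",
            f"Capture rate:     {self.params.capture_rate:>6.3f}    Seed: {self.seed}",
            "-" * 57,
            f"{'parameter':<22}{'estimate':>16}{'(log10 form)':>16}",
            "-" * 57,
        ]
        for name, val, alt in rows:
            lines.append(f"{name:<22}{val:>16.4g}{alt:>16}")
        lines.append("=" * 57)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<MosquitoPopulationResults llf={self.llf:.2f} seed={self.seed}>"
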