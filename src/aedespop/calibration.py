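"""Poisson-likelihood calibration by simulated-annealing Metropolis search.

Weekly trap counts of adult females are modelled as Poisson with mean
``lambda_w = capture_rate * (mean daily adult abundance over the 7-day
block w)``; captures are assumed not to deplete the population.  The free
parameters — by default the maximum carrying capacity kappa_max and the
eight diapause sigmoid parameters — are searched with a Metropolis random
walk whose acceptance temperature follows a geometric cooling schedule.
kappa_max and the four sigmoid slopes are searched in log10 space, the four
half-saturation points on their natural (linear) scale.

The forward model is re-run for every proposal, so the objective
precomputes everything that does not depend on the free parameters (thermal
rates, soil-moisture ratio, week/observation bookkeeping) once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .environment import week_of_year
from .exceptions import CalibrationError, CoverageError
from .population import (
    ModelParams,
    PopulationState,
    _integrate,
    diapause_induction_prob,
    diapause_termination_prob,
)

LAMBDA_FLOOR = 1e-9

#: default search space: name -> (transform, lower, upper, proposal sd)
#: bounds on the transformed scale; beta_t1 capped at 30 degC.
DEFAULT_PARAM_SPACE = {
    "kappa_max": ("log10", 0.0, 4.0, 0.05),
    "alpha_d1": ("log10", 0.0, 6.0, 0.3),
    "alpha_d2": ("log10", 0.0, 6.0, 0.3),
    "alpha_t1": ("log10", 0.0, 6.0, 0.3),
    "alpha_t2": ("log10", 0.0, 6.0, 0.3),
    "beta_d1": ("linear", 10.0, 18.0, 0.1),
    "beta_d2": ("linear", 8.0, 16.0, 0.1),
    "beta_t1": ("linear", 5.0, 30.0, 0.5),
    "beta_t2": ("linear", 0.0, 25.0, 0.5),
}


@dataclass
class CalibrationConfig:
    """Settings of the annealing search.

    ``param_space`` maps parameter names to ``(transform, low, high,
    proposal_sd)`` with bounds and proposal widths on the transformed
    scale.  ``initial_temp=None`` picks the temperature at which about half
    of the initial proposals would be accepted (median |delta log-lik| of a
    probe sample divided by ln 2).
    """

    param_space: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_SPACE))
    initial_temp: float | None = None
    cooling: float = 0.95
    iters_per_level: int = 200
    n_levels: int = 60
    seed: int = 0
    burn_in_years: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        for name, (transform, lo, hi, sd) in self.param_space.items():
            if not np.isfinite([lo, hi]).all() or lo >= hi:
                raise ValueError(f"bad bounds for {name}")
            if transform not in ("log10", "linear"):
                raise ValueError(f"unknown transform {transform!r} for {name}")


@dataclass
class CalibrationResult:
    """Best parameters found plus the search traces."""

    params: ModelParams
    log_likelihood: float
    loglik_trace: np.ndarray
    best_trace: np.ndarray
    acceptance_rate: np.ndarray  # one entry per temperature level
    seed: int
    n_iterations: int


def _get_param(params: ModelParams, name: str) -> float:
    if name == "kappa_max":
        return params.capacity.kappa_max
    if name == "nu":
        return params.capacity.nu
    return getattr(params.diapause, name)


def _set_params(params: ModelParams, updates: dict) -> ModelParams:
    cap = {k: v for k, v in updates.items() if k in ("kappa_max", "nu")}
    dia = {k: v for k, v in updates.items() if k not in ("kappa_max", "nu")}
    out = params
    if cap:
        out = replace(out, capacity=replace(out.capacity, **cap))
    if dia:
        out = replace(out, diapause=replace(out.diapause, **dia))
    return out


def expected_weekly_capture(
    trajectory: pd.DataFrame, observations: pd.DataFrame, capture_rate: float
) -> np.ndarray:
    """Expected count lambda_w for each observation row.

    lambda_w = capture_rate * mean(daily A over the observation's 7-day
    block), floored at 1e-9 so the Poisson likelihood stays finite when the
    simulated population is extinct.
    """
    dates = pd.DatetimeIndex(trajectory["date"])
    traj_year = dates.year.to_numpy()
    traj_week = week_of_year(dates)
    a = trajectory["A"].to_numpy(dtype=float)
    lam = np.empty(len(observations))
    for i, (year, week) in enumerate(zip(observations["year"], observations["week"])):
        mask = (traj_year == year) & (traj_week == week)
        if not mask.any():
            raise CoverageError(f"trajectory does not cover year {year} week {week}")
        lam[i] = capture_rate * a[mask].mean()
    return np.maximum(lam, LAMBDA_FLOOR)


def poisson_log_likelihood(counts, lam) -> float:
    """Sum over weeks of n ln(lambda) - lambda - ln(n!)."""
    n = np.asarray(counts, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if n.shape != lam.shape:
        raise ValueError("counts and lambda series differ in length")
    if np.any(n < 0):
        raise ValueError("negative count")
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    return float(np.sum(n * np.log(lam) - lam - gammaln(n + 1.0)))


def period_log_likelihood(
    observations: pd.DataFrame, lam, week_ranges: list[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """Per-period mean annual log-likelihood over week ranges.

    For each (first_week, last_week) range the Poisson log-likelihood is
    summed over the observations inside the range and divided by the number
    of years represented in the observation set.
    """
    lam = np.asarray(lam, dtype=float)
    counts = observations["count"].to_numpy(dtype=float)
    weeks = observations["week"].to_numpy()
    n_years = observations["year"].nunique()
    out = {}
    for lo, hi in week_ranges:
        if not (1 <= lo <= hi <= 53):
            raise ValueError(f"invalid week range {(lo, hi)}")
        mask = (weeks >= lo) & (weeks <= hi)
        if not mask.any():
            out[(lo, hi)] = float("nan")
            continue
        out[(lo, hi)] = poisson_log_likelihood(counts[mask], lam[mask]) / n_years
    return out


class LikelihoodEvaluator:
    """Fast re-evaluation of the trap-count log-likelihood.

    Precomputes thermal rate arrays, soil-moisture ratio and the
    observation-to-day index map once; ``loglik(params)`` then only
    recomputes the diapause gates, K, the forward integration and the
    weekly means.
    """

    def __init__(
        self,
        env: pd.DataFrame,
        observations: pd.DataFrame,
        base_params: ModelParams,
        initial_state: PopulationState | None = None,
    ):
        self.env = env.reset_index(drop=True)
        self.base_params = base_params
        self.initial_state = initial_state or PopulationState(E_dia=1000.0)
        th = base_params.thermal
        tw = self.env["t_water"].to_numpy(dtype=float)
        ta = self.env["t_air"].to_numpy(dtype=float)
        self._rates = (
            th.o_v(ta), th.d_E(tw), th.d_L(tw), th.d_P(tw),
            th.m_E(tw), th.m_L(tw), th.m_P(tw), th.m_A(ta),
        )
        self._w_ratio = self.env["soil_water"].to_numpy(dtype=float) / float(
            self.env["w_star"].iloc[0]
        )
        self._d_week = self.env["d_week"].to_numpy(dtype=float)
        self._ta_week = self.env["ta_week"].to_numpy(dtype=float)
        self._tw_week = self.env["tw_week"].to_numpy(dtype=float)
        self._delta_d = self.env["delta_d"].to_numpy(dtype=float)
        dates = pd.DatetimeIndex(self.env["date"])
        yw = list(zip(dates.year.to_numpy(), week_of_year(dates)))
        groups: dict[tuple[int, int], list[int]] = {}
        for i, key in enumerate(yw):
            groups.setdefault(key, []).append(i)
        self.observations = observations.reset_index(drop=True)
        self._obs_counts = self.observations["count"].to_numpy(dtype=float)
        self._obs_days = []
        for year, week in zip(self.observations["year"], self.observations["week"]):
            key = (int(year), int(week))
            if key not in groups:
                raise CoverageError(f"environment does not cover year {year} week {week}")
            self._obs_days.append(np.asarray(groups[key], dtype=np.intp))
        self._ln_fact = float(np.sum(gammaln(self._obs_counts + 1.0)))

    def adult_series(self, params: ModelParams) -> np.ndarray:
        from .population import K_FLOOR

        z1 = diapause_induction_prob(self._d_week, self._ta_week, self._delta_d, params.diapause)
        z2 = diapause_termination_prob(self._d_week, self._tw_week, self._delta_d, params.diapause)
        k = np.maximum(params.capacity.kappa_max * self._w_ratio ** params.capacity.nu, K_FLOOR)
        ov, d_e, d_l, d_p, m_e, m_l, m_p, m_a = self._rates
        out = _integrate(
            ov, z1, z2, d_e, d_l, d_p, m_e, m_l, m_p, m_a, k,
            self.initial_state.as_array(), 1,
        )
        return out[:, 4]

    def expected_captures(self, params: ModelParams) -> np.ndarray:
        a = self.adult_series(params)
        lam = np.array([params.capture_rate * a[idx].mean() for idx in self._obs_days])
        return np.maximum(lam, LAMBDA_FLOOR)

    def loglik(self, params: ModelParams) -> float:
        lam = self.expected_captures(params)
        return float(np.sum(self._obs_counts * np.log(lam) - lam)) - self._ln_fact


def calibrate(
    observations: pd.DataFrame,
    env: pd.DataFrame,
    base_params: ModelParams,
    config: CalibrationConfig,
) -> CalibrationResult:
    """Fit the free parameters to weekly trap counts.

    Metropolis random walk in the transformed parameter space: a Gaussian
    proposal perturbs every free parameter, out-of-bounds proposals are
    rejected outright, and in-bounds proposals are accepted with
    probability min(1, exp(delta_loglik / T)).  The temperature follows a
    geometric schedule; the best-ever candidate is returned.  The run is
    reproducible bit-for-bit given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    evaluator = LikelihoodEvaluator(env, observations, base_params)
    names = list(config.param_space)
    transforms = {n: config.param_space[n][0] for n in names}

    def to_search(name, value):
        return np.log10(value) if transforms[name] == "log10" else value

    def from_search(name, value):
        return float(10.0**value) if transforms[name] == "log10" else float(value)

    theta = np.array([to_search(n, _get_param(base_params, n)) for n in names])
    lo = np.array([config.param_space[n][1] for n in names])
    hi = np.array([config.param_space[n][2] for n in names])
    sd = np.array([config.param_space[n][3] for n in names])
    theta = np.clip(theta, lo, hi)

    def make_params(vec):
        return _set_params(base_params, {n: from_search(n, v) for n, v in zip(names, vec)})

    current_ll = evaluator.loglik(make_params(theta))
    best_theta, best_ll = theta.copy(), current_ll

    temp = config.initial_temp
    if temp is None:
        probes = []
        for _ in range(30):
            cand = theta + rng.normal(0.0, sd)
            if np.all(cand >= lo) and np.all(cand <= hi):
                probes.append(abs(evaluator.loglik(make_params(cand)) - current_ll))
        med = float(np.median(probes)) if probes else 1.0
        temp = max(med / np.log(2.0), 1e-6)

    n_total = config.n_levels * config.iters_per_level
    ll_trace = np.empty(n_total)
    best_trace = np.empty(n_total)
    acc_rate = np.empty(config.n_levels)
    it = 0
    for level in range(config.n_levels):
        accepted = 0
        for _ in range(config.iters_per_level):
            cand = theta + rng.normal(0.0, sd)
            accept = False
            if np.all(cand >= lo) and np.all(cand <= hi):
                cand_ll = evaluator.loglik(make_params(cand))
                delta = cand_ll - current_ll
                if delta >= 0 or rng.random() < np.exp(delta / temp):
                    accept = True
            if accept:
                theta, current_ll = cand, cand_ll
                accepted += 1
                if current_ll > best_ll:
                    best_theta, best_ll = theta.copy(), current_ll
            ll_trace[it] = current_ll
            best_trace[it] = best_ll
            it += 1
        acc_rate[level] = accepted / max(config.iters_per_level, 1)
        if level == 0 and config.iters_per_level > 0 and accepted == 0:
            raise CalibrationError(
                "no proposal accepted at the initial temperature; "
                "reduce the proposal scales or raise initial_temp"
            )
        temp *= config.cooling
    return CalibrationResult(
        params=make_params(best_theta),
        log_likelihood=best_ll,
        loglik_trace=ll_trace[:it],
        best_trace=best_trace[:it],
        acceptance_rate=acc_rate[: config.n_levels if it else 0],
        seed=config.seed,
        n_iterations=it,
    )
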