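"""The stage-structured population core.

Five continuous stage abundances — active eggs E, diapausing eggs E_dia,
larvae L, pupae P and adult females A — obey

    dE/dt     = (1 - z1) o_v A - (m_E + d_E) E + z2 E_dia
    dE_dia/dt = z1 o_v A - z2 E_dia
    dL/dt     = d_E E - (m_L + d_L + L/K) L
    dP/dt     = d_L L - (m_P + d_P) P
    dA/dt     = d_P P - m_A A

with temperature-dependent development rates d_i and mortalities m_i
(aquatic stages at water temperature, adults and oviposition at air
temperature), a larval crowding term L/K, and two environmental gates:

* z1, the probability a freshly laid egg enters diapause, active only while
  days are shortening (dD < 0) and rising as the 7-day photoperiod and air
  temperature fall below their half-saturation points;
* z2, the daily diapause-termination probability, active only while days
  are lengthening (dD > 0) and rising as the 7-day photoperiod and *water*
  temperature exceed their half-saturation points.

The larval carrying capacity K tracks soil moisture,
``K = kappa_max * (W/W*)**nu``; nu = 0 fixes K at kappa_max.

Integration is classical RK4 with the day's environment held constant
(daily forcing is the resolution of the data); the inner loop is compiled
with numba because calibration evaluates tens of thousands of multi-year
forward runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .exceptions import InvalidCapacityError, NumericalInstabilityError
from .thermal import ThermalResponseSet

STATE_NAMES = ("E", "E_dia", "L", "P", "A")

#: floor applied to K so the crowding term stays finite on bone-dry soil
K_FLOOR = 1e-6


@dataclass(frozen=True)
class PopulationState:
    """Abundances of the five stages (continuous, nonnegative)."""

    E: float = 0.0
    E_dia: float = 0.0
    L: float = 0.0
    P: float = 0.0
    A: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.E_dia, self.L, self.P, self.A])

    @classmethod
    def from_array(cls, x) -> "PopulationState":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class DiapauseParams:
    """Slopes (alpha, per h or per degC) and half-saturation points (beta)
    of the two diapause sigmoids.

    Index 1 = induction (short-day gate), index 2 = termination
    (long-day gate); d = photoperiod, t = temperature.  Defaults are the
    Tokyo fit of the rainfall-responsive model variant.
    """

    alpha_d1: float = 10.0**5.10
    alpha_d2: float = 10.0**3.84
    alpha_t1: float = 10.0**4.70
    alpha_t2: float = 10.0**2.42
    beta_d1: float = 14.420
    beta_d2: float = 11.518
    beta_t1: float = 28.822
    beta_t2: float = 9.458

    def __post_init__(self) -> None:
        for a in ("alpha_d1", "alpha_d2", "alpha_t1", "alpha_t2"):
            if getattr(self, a) <= 0:
                raise ValueError(f"{a} must be positive")
        for b in ("beta_d1", "beta_d2"):
            if not 0 < getattr(self, b) < 24:
                raise ValueError(f"{b} must lie in (0, 24) h")


@dataclass(frozen=True)
class CarryingCapacityParams:
    """Maximum larval carrying capacity and soil-moisture responsiveness.

    The default kappa_max is sized so that, with the default thermal
    curves and a 1 % capture rate, simulated weekly captures peak in the
    tens — the order observed in urban dry-ice trap series.
    """

    kappa_max: float = 2000.0
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa_max <= 0:
            raise ValueError("kappa_max must be positive")
        if self.nu < 0:
            raise ValueError("nu must be nonnegative")


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the population model."""

    diapause: DiapauseParams = field(default_factory=DiapauseParams)
    capacity: CarryingCapacityParams = field(default_factory=CarryingCapacityParams)
    thermal: ThermalResponseSet = field(default_factory=ThermalResponseSet)
    capture_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.capture_rate <= 1:
            raise ValueError("capture_rate must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "diapause": asdict(self.diapause),
            "capacity": asdict(self.capacity),
            "thermal": self.thermal.to_dict(),
            "capture_rate": self.capture_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            diapause=DiapauseParams(**d["diapause"]),
            capacity=CarryingCapacityParams(**d["capacity"]),
            thermal=ThermalResponseSet.from_dict(d["thermal"]),
            capture_rate=d.get("capture_rate", 0.01),
        )


def carrying_capacity(soil_water, w_star: float, params: CarryingCapacityParams):
    """Larval carrying capacity K = kappa_max (W/W*)^nu, floored at 1e-6.

    The floor is a dry-soil refuge of negligible size that keeps the L/K
    crowding term finite when W = 0 and nu > 0.
    """
    w = np.asarray(soil_water, dtype=float)
    if w_star <= 0:
        raise InvalidCapacityError("w_star must be positive")
    if np.any(w < 0) or np.any(w > w_star * (1 + 1e-9)):
        raise InvalidCapacityError("soil water outside [0, w_star]")
    k = params.kappa_max * (np.minimum(w, w_star) / w_star) ** params.nu
    k = np.maximum(k, K_FLOOR)
    return float(k) if k.ndim == 0 else k


def diapause_induction_prob(d_week, ta_week, delta_d, params: DiapauseParams):
    """Probability z1 that a freshly laid egg enters diapause.

    Zero unless days are shortening (delta_d < 0); otherwise the product of
    a falling-photoperiod sigmoid and a falling-air-temperature sigmoid,
    each equal to 1/2 at its beta.  Computed with the logistic function so
    slopes up to 1e6 cannot overflow.
    """
    z = expit(params.alpha_d1 * (params.beta_d1 - np.asarray(d_week, dtype=float))) * expit(
        params.alpha_t1 * (params.beta_t1 - np.asarray(ta_week, dtype=float))
    )
    out = np.where(np.asarray(delta_d) < 0, z, 0.0)
    return float(out) if out.ndim == 0 else out


def diapause_termination_prob(d_week, tw_week, delta_d, params: DiapauseParams):
    """Daily probability z2 that a diapausing egg resumes development.

    Zero unless days are lengthening (delta_d > 0); otherwise the product
    of a rising-photoperiod sigmoid and a rising-*water*-temperature
    sigmoid (hatching is cued by the larval habitat, not the air).
    """
    z = expit(params.alpha_d2 * (np.asarray(d_week, dtype=float) - params.beta_d2)) * expit(
        params.alpha_t2 * (np.asarray(tw_week, dtype=float) - params.beta_t2)
    )
    out = np.where(np.asarray(delta_d) > 0, z, 0.0)
    return float(out) if out.ndim == 0 else out


def threshold_diapause(
    ta_week,
    d_week,
    induction_t: float = 21.0,
    induction_d: float = 13.5,
    break_t: float = 10.5,
    break_d: float = 10.25,
):
    """Hard-switch alternative to the sigmoid gates.

    Diapause is induced when both weekly means fall below their cut-offs
    (Ta_week < 21 degC and D_week < 13.5 h by default) and broken when both
    exceed theirs (Ta_week > 10.5 degC and D_week > 10.25 h).  Returns
    ``(diapause_on, break_on)`` booleans usable as z1/z2 in {0, 1}.
    """
    ta = np.asarray(ta_week, dtype=float)
    d = np.asarray(d_week, dtype=float)
    on = (ta < induction_t) & (d < induction_d)
    off = (ta > break_t) & (d > break_d)
    if on.ndim == 0:
        return bool(on), bool(off)
    return on, off


def derivatives(state: PopulationState, env, params: ModelParams):
    """Right-hand side of the stage ODEs for one environment day.

    ``env`` is a mapping (or DataFrame row) with fields ``t_air, t_water,
    soil_water, w_star, d_week, ta_week, tw_week, delta_d``.  Returns the
    five rates of change (per day) in stage order.
    """
    tw = float(env["t_water"])
    ta = float(env["t_air"])
    th = params.thermal
    k = carrying_capacity(float(env["soil_water"]), float(env["w_star"]), params.capacity)
    if k <= 0:
        raise InvalidCapacityError(f"carrying capacity {k} <= 0")
    z1 = diapause_induction_prob(env["d_week"], env["ta_week"], env["delta_d"], params.diapause)
    z2 = diapause_termination_prob(env["d_week"], env["tw_week"], env["delta_d"], params.diapause)
    ov, d_e, d_l, d_p = th.o_v(ta), th.d_E(tw), th.d_L(tw), th.d_P(tw)
    m_e, m_l, m_p, m_a = th.m_E(tw), th.m_L(tw), th.m_P(tw), th.m_A(ta)
    e, e_dia, l, p, a = state.E, state.E_dia, state.L, state.P, state.A
    return (
        (1.0 - z1) * ov * a - (m_e + d_e) * e + z2 * e_dia,
        z1 * ov * a - z2 * e_dia,
        d_e * e - (m_l + d_l + l / k) * l,
        d_l * l - (m_p + d_p) * p,
        d_p * p - m_a * a,
    )


@njit(cache=False)
def _deriv(e, ed, l, p, a, ov, z1, z2, de, dl, dp, me, ml, mp, ma, k):  # pragma: no cover
    f0 = (1.0 - z1) * ov * a - (me + de) * e + z2 * ed
    f1 = z1 * ov * a - z2 * ed
    f2 = de * e - (ml + dl + l / k) * l
    f3 = dl * l - (mp + dp) * p
    f4 = dp * p - ma * a
    return f0, f1, f2, f3, f4


@njit(cache=False)
def _integrate(ov, z1, z2, d_e, d_l, d_p, m_e, m_l, m_p, m_a, k, y0, n_sub):  # pragma: no cover
    """RK4 over the whole series; one row of output per day (end of day)."""
    n = ov.shape[0]
    out = np.empty((n, 5))
    e, ed, l, p, a = y0[0], y0[1], y0[2], y0[3], y0[4]
    dt = 1.0 / n_sub
    for i in range(n):
        c = (ov[i], z1[i], z2[i], d_e[i], d_l[i], d_p[i], m_e[i], m_l[i], m_p[i], m_a[i], k[i])
        for _ in range(n_sub):
            a1, b1, c1, dd1, e1 = _deriv(e, ed, l, p, a, *c)
            a2, b2, c2, dd2, e2 = _deriv(
                e + 0.5 * dt * a1, ed + 0.5 * dt * b1, l + 0.5 * dt * c1,
                p + 0.5 * dt * dd1, a + 0.5 * dt * e1, *c
            )
            a3, b3, c3, dd3, e3 = _deriv(
                e + 0.5 * dt * a2, ed + 0.5 * dt * b2, l + 0.5 * dt * c2,
                p + 0.5 * dt * dd2, a + 0.5 * dt * e2, *c
            )
            a4, b4, c4, dd4, e4 = _deriv(
                e + dt * a3, ed + dt * b3, l + dt * c3, p + dt * dd3, a + dt * e3, *c
            )
            e += dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            ed += dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            l += dt / 6.0 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
            p += dt / 6.0 * (dd1 + 2.0 * dd2 + 2.0 * dd3 + dd4)
            a += dt / 6.0 * (e1 + 2.0 * e2 + 2.0 * e3 + e4)
        if e < 0.0:
            e = 0.0
        if ed < 0.0:
            ed = 0.0
        if l < 0.0:
            l = 0.0
        if p < 0.0:
            p = 0.0
        if a < 0.0:
            a = 0.0
        out[i, 0] = e
        out[i, 1] = ed
        out[i, 2] = l
        out[i, 3] = p
        out[i, 4] = a
    return out


def _daily_coefficients(env: pd.DataFrame, params: ModelParams):
    """Precompute every state-independent daily coefficient array."""
    tw = env["t_water"].to_numpy(dtype=float)
    ta = env["t_air"].to_numpy(dtype=float)
    th = params.thermal
    z1 = diapause_induction_prob(
        env["d_week"].to_numpy(), env["ta_week"].to_numpy(), env["delta_d"].to_numpy(), params.diapause
    )
    z2 = diapause_termination_prob(
        env["d_week"].to_numpy(), env["tw_week"].to_numpy(), env["delta_d"].to_numpy(), params.diapause
    )
    k = carrying_capacity(
        env["soil_water"].to_numpy(), float(env["w_star"].iloc[0]), params.capacity
    )
    k = np.broadcast_to(np.asarray(k, dtype=float), tw.shape).copy()
    return (
        th.o_v(ta), np.asarray(z1, float), np.asarray(z2, float),
        th.d_E(tw), th.d_L(tw), th.d_P(tw),
        th.m_E(tw), th.m_L(tw), th.m_P(tw), th.m_A(ta),
        k,
    )


def step_population(
    state: PopulationState, env, params: ModelParams, dt: float = 1.0
) -> PopulationState:
    """Advance one day by RK4 with the day's environment held constant.

    ``dt`` (days) sets the RK4 sub-step; dt = 1 is a single step per day.
    Components are clamped at zero after the day.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    env_df = pd.DataFrame([dict(env)]) if not isinstance(env, pd.DataFrame) else env
    coeffs = _daily_coefficients(env_df.iloc[:1].assign(w_star=float(env_df["w_star"].iloc[0])), params)
    n_sub = max(int(round(1.0 / dt)), 1)
    out = _integrate(*coeffs, state.as_array(), n_sub)
    if not np.all(np.isfinite(out)):
        raise NumericalInstabilityError("non-finite state after one step")
    return PopulationState.from_array(out[0])


def simulate(
    env: pd.DataFrame,
    params: ModelParams,
    initial_state: PopulationState | None = None,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Integrate the stage ODEs over a daily environment table.

    Parameters
    ----------
    env : DataFrame
        Output of :func:`aedespop.environment.build_environment` (gap-free).
    params : ModelParams
    initial_state : PopulationState, optional
        Defaults to 1000 diapausing eggs and nothing else — the
        overwintering stock on a January 1 start.
    dt : float
        RK4 sub-step in days (1/dt sub-steps per day).

    Returns
    -------
    DataFrame with ``date``, the five stages, and the diagnostic columns
    ``K, z1, z2``; one row per day (state at the end of the day).
    """
    if initial_state is None:
        initial_state = PopulationState(E_dia=1000.0)
    coeffs = _daily_coefficients(env, params)
    n_sub = max(int(round(1.0 / dt)), 1)
    out = _integrate(*coeffs, initial_state.as_array(), n_sub)
    if not np.all(np.isfinite(out)):
        day = int(np.flatnonzero(~np.isfinite(out).all(axis=1))[0])
        raise NumericalInstabilityError(
            f"non-finite state on day {day} ({env['date'].iloc[day].date()})"
        )
    traj = pd.DataFrame(out, columns=list(STATE_NAMES))
    traj.insert(0, "date", pd.DatetimeIndex(env["date"]).to_numpy())
    traj["K"] = coeffs[10]
    traj["z1"] = coeffs[1]
    traj["z2"] = coeffs[2]
    return traj


def equilibrium_larvae(env_row, params: ModelParams) -> float:
    """Closed-form larval equilibrium under a constant benign environment.

    With z1 = z2 = 0 and constant rates the steady state satisfies
    L* = K (d_E o_v d_P d_L / ((m_E + d_E)(m_P + d_P) m_A) - m_L - d_L);
    positive only when the stage-cycle reproduction number exceeds the
    density-independent larval loss.
    """
    th = params.thermal
    tw, ta = float(env_row["t_water"]), float(env_row["t_air"])
    k = carrying_capacity(float(env_row["soil_water"]), float(env_row["w_star"]), params.capacity)
    gain = (
        th.d_E(tw) * th.o_v(ta) * th.d_P(tw) * th.d_L(tw)
        / ((th.m_E(tw) + th.d_E(tw)) * (th.m_P(tw) + th.d_P(tw)) * th.m_A(ta))
    )
    return k * (gain - th.m_L(tw) - th.d_L(tw))
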