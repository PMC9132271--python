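"""Parametric thermal-response curves for development, mortality, oviposition.

The population model needs, for each aquatic stage, a temperature-dependent
development rate and mortality rate, plus adult mortality and a per-capita
oviposition rate.  These are represented as small parametric curve objects:

* :class:`BriereCurve` — the left-skewed unimodal form
  ``c * T * (T - t_min) * sqrt(t_max - T)`` standard for insect development
  rates; zero outside (t_min, t_max).
* :class:`QuadraticCurve` — symmetric hump ``c * (T - t_min) * (t_max - T)``,
  used here for oviposition.
* :class:`UShapedMortality` — ``m_min * exp(((T - t_opt)/scale)^2)``, a
  U-shaped rate with a strictly positive floor at the thermal optimum.

The default set below is a literature-informed, field-leaning
parameterisation for *Aedes albopictus* at daily resolution (rates per
day, temperatures degC): egg/larva/pupa development peaking near 28-32
degC with durations of roughly 7, 10 and 3 days at 25 degC; mortality
floors of 3-4 %/day for the aquatic stages and 10 %/day for adults
(field survival is far below laboratory survival), rising steeply and
capped at 1/day toward the thermal extremes; and an effective oviposition
rate peaking at about 2 female eggs per female per day at 25 degC.  Every
curve is overridable from configuration; the model's qualitative behaviour
(seasonal cycle, diapause timing, capacity response) does not hinge on the
exact coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class BriereCurve:
    """Briere development-rate curve (per day), zero outside (t_min, t_max)."""

    coeff: float
    t_min: float
    t_max: float
    shape: str = "briere"

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.zeros_like(t)
        inside = (t > self.t_min) & (t < self.t_max)
        ti = t[inside]
        out[inside] = self.coeff * ti * (ti - self.t_min) * np.sqrt(self.t_max - ti)
        out = np.maximum(out, 0.0)
        return float(out[0]) if scalar else out


@dataclass(frozen=True)
class QuadraticCurve:
    """Symmetric quadratic hump (per day), zero outside (t_min, t_max)."""

    coeff: float
    t_min: float
    t_max: float
    shape: str = "quadratic"

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.maximum(self.coeff * (t - self.t_min) * (self.t_max - t), 0.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class UShapedMortality:
    """Exponential-quadratic mortality rate with positive floor ``m_min``.

    The rate is capped at ``m_max`` (default 1/day): faster mortality is
    not resolvable under daily forcing, and the cap keeps the stage ODEs
    inside the stability region of a daily Runge-Kutta step even at
    temperature extremes.
    """

    m_min: float
    t_opt: float
    scale: float
    m_max: float = 1.0
    shape: str = "u_exp_quadratic"

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.minimum(self.m_min * np.exp(((t - self.t_opt) / self.scale) ** 2), self.m_max)
        return float(out) if out.ndim == 0 else out


_CURVE_CLASSES = {
    "briere": BriereCurve,
    "quadratic": QuadraticCurve,
    "u_exp_quadratic": UShapedMortality,
}


def curve_from_dict(d: dict):
    """Rebuild a curve from its ``asdict`` representation."""
    d = dict(d)
    cls = _CURVE_CLASSES[d.pop("shape")]
    return cls(**d)


@dataclass(frozen=True)
class ThermalResponseSet:
    """The full set of thermal-response curves used by the stage ODEs.

    Aquatic rates (d_E, d_L, d_P, m_E, m_L, m_P) are evaluated at water
    temperature; aerial rates (m_A, o_v) at air temperature.
    """

    d_E: BriereCurve = field(default_factory=lambda: BriereCurve(1.05e-4, 10.0, 38.0))
    d_L: BriereCurve = field(default_factory=lambda: BriereCurve(7.4e-5, 10.0, 38.0))
    d_P: BriereCurve = field(default_factory=lambda: BriereCurve(2.5e-4, 10.0, 38.0))
    m_E: UShapedMortality = field(default_factory=lambda: UShapedMortality(0.03, 22.0, 14.0))
    m_L: UShapedMortality = field(default_factory=lambda: UShapedMortality(0.04, 25.0, 12.0))
    m_P: UShapedMortality = field(default_factory=lambda: UShapedMortality(0.04, 25.0, 12.0))
    m_A: UShapedMortality = field(default_factory=lambda: UShapedMortality(0.10, 25.0, 12.0))
    o_v: QuadraticCurve = field(default_factory=lambda: QuadraticCurve(0.0089, 10.0, 40.0))

    def to_dict(self) -> dict:
        return {k: asdict(getattr(self, k)) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ThermalResponseSet":
        return cls(**{k: curve_from_dict(v) for k, v in d.items()})
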