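"""Physical and physiological unit layer for treadmill roller-skiing energetics.

Implements the chain of conversions every estimator in this package rests on:
mechanical power output on a graded treadmill (gravity + rolling resistance),
indirect-calorimetry energy conversion from oxygen uptake and the respiratory
exchange ratio (Weir equation), energy cost per metre, gross and net
efficiency, and the joule <-> mL O2-equivalent conversion at RER 1.00.

Units follow the conventions of treadmill roller-skiing studies: speeds are
accepted in km/h at most interfaces and converted internally to m/s, oxygen
uptake is in L/min, and rates are in W (or W per kg *system* mass, i.e. the
athlete plus roller skis and poles — the mass the power model acts on).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, model_validator

__all__ = [
    "KMH_TO_MS",
    "O2_EQ_ML_PER_J",
    "TestConditions",
    "BaselineMeasurement",
    "StageMeasurement",
    "kmh_to_ms",
    "power_output",
    "metabolic_rate_weir",
    "energy_cost",
    "gross_efficiency",
    "net_efficiency",
    "o2_equivalent",
]

#: km/h -> m/s conversion factor.
KMH_TO_MS = 1.0 / 3.6

#: mL of O2 equivalent per joule of metabolic energy, assuming 100%
#: carbohydrate oxidation (RER = 1.00). This is the exact inverse of the Weir
#: energy yield per litre of O2 at RER 1.00: 1000 / (4184 * (1.1*1.00 + 3.9)).
#: Printed to 5 significant figures it is the familiar 0.047801 mL/J.
O2_EQ_ML_PER_J = 1000.0 / (4184.0 * (1.1 * 1.00 + 3.9))

# Physiological bounds on the respiratory exchange ratio accepted by the Weir
# conversion; values outside indicate a measurement or bookkeeping error.
_RER_MIN, _RER_MAX = 0.6, 1.3


class TestConditions(BaseModel):
    """Treadmill and mass configuration of a test session.

    Attributes
    ----------
    incline_deg:
        Treadmill incline angle alpha, degrees. Must lie in [0, 45).
    mu_r:
        Coefficient of rolling resistance of the roller skis (dimensionless).
    gravity:
        Gravitational acceleration, m/s^2.
    body_mass_kg:
        Athlete body mass (BM), kg.
    system_mass_kg:
        Athlete plus equipment mass (m_sys), kg. The treadmill power model
        acts on the system mass, so ``system_mass_kg >= body_mass_kg``.
    """

    __test__ = False  # "Test" refers to the exercise test, not pytest

    incline_deg: float
    mu_r: float
    body_mass_kg: float
    system_mass_kg: float
    gravity: float = 9.81

    @model_validator(mode="after")
    def _check(self) -> "TestConditions":
        if not (0.0 <= self.incline_deg < 45.0):
            raise ValueError(f"incline_deg must be in [0, 45), got {self.incline_deg}")
        if self.mu_r < 0.0:
            raise ValueError(f"mu_r must be >= 0, got {self.mu_r}")
        if not (self.body_mass_kg > 0.0):
            raise ValueError("body_mass_kg must be positive")
        if self.system_mass_kg < self.body_mass_kg:
            raise ValueError("system_mass_kg must be >= body_mass_kg")
        return self

    @property
    def incline_rad(self) -> float:
        return math.radians(self.incline_deg)

    def power_per_kg_per_ms(self) -> float:
        """Power per kg system mass per unit speed (W·kg⁻¹ per m·s⁻¹).

        The treadmill power model is linear in speed, so this single factor
        g·(sin α + μR·cos α) fully characterises the mechanical demand side.
        """
        a = self.incline_rad
        return self.gravity * (math.sin(a) + self.mu_r * math.cos(a))


class BaselineMeasurement(BaseModel):
    """Standing-rest gas exchange: VO2 (L/min) and RER."""

    vo2_l_min: float
    rer: float

    @model_validator(mode="after")
    def _check(self) -> "BaselineMeasurement":
        if self.vo2_l_min < 0.0:
            raise ValueError("vo2_l_min must be >= 0")
        if not (_RER_MIN <= self.rer <= _RER_MAX):
            raise ValueError(f"rer must be in [{_RER_MIN}, {_RER_MAX}], got {self.rer}")
        return self

    def metabolic_rate_w(self) -> float:
        return metabolic_rate_weir(self.vo2_l_min, self.rer)


class StageMeasurement(BaseModel):
    """Final-minute averages for one submaximal stage.

    ``rer`` is the final-minute mean respiratory exchange ratio; for the
    metabolic-rate conversion it should not exceed 1.00 (steady state below
    the second ventilatory threshold).
    """

    speed_kmh: float
    vo2_l_min: float
    rer: float
    hr_bpm: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "StageMeasurement":
        if self.speed_kmh <= 0.0:
            raise ValueError("speed_kmh must be positive")
        if self.vo2_l_min < 0.0:
            raise ValueError("vo2_l_min must be >= 0")
        if not (_RER_MIN <= self.rer <= _RER_MAX):
            raise ValueError(f"rer must be in [{_RER_MIN}, {_RER_MAX}], got {self.rer}")
        return self

    def metabolic_rate_w(self) -> float:
        return metabolic_rate_weir(self.vo2_l_min, self.rer)

    def power_w(self, cond: TestConditions) -> float:
        return power_output(kmh_to_ms(self.speed_kmh), cond)


def kmh_to_ms(speed_kmh):
    """Convert a speed (scalar or array) from km/h to m/s."""
    return np.asarray(speed_kmh, dtype=float) * KMH_TO_MS if np.ndim(speed_kmh) else float(speed_kmh) * KMH_TO_MS


def power_output(speed_ms, cond: TestConditions):
    """Mechanical power output [W] on a graded treadmill.

    P = v * m_sys * g * (sin(alpha) + mu_R * cos(alpha)) — the sum of the
    power against gravity and against rolling resistance. Accepts a scalar
    or array speed in m/s; strictly proportional to speed and system mass.
    """
    v = np.asarray(speed_ms, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed_ms must be >= 0")
    p = v * cond.system_mass_kg * cond.power_per_kg_per_ms()
    return float(p) if np.ndim(speed_ms) == 0 else p


def metabolic_rate_weir(vo2_l_min, rer):
    """Metabolic rate [W] from VO2 (L/min) and RER via the Weir equation.

    MR = 4184 * VO2 * (1.1*RER + 3.9) / 60. The term (1.1*RER + 3.9) is the
    caloric equivalent of one litre of O2 in kcal, interpolating between pure
    fat (RER 0.70) and pure carbohydrate (RER 1.00) oxidation.
    """
    vo2 = np.asarray(vo2_l_min, dtype=float)
    r = np.asarray(rer, dtype=float)
    if np.any(vo2 < 0):
        raise ValueError("vo2_l_min must be >= 0")
    if np.any((r < _RER_MIN) | (r > _RER_MAX)):
        raise ValueError(f"rer must be in [{_RER_MIN}, {_RER_MAX}]")
    mr = 4184.0 * vo2 * (1.1 * r + 3.9) / 60.0
    return float(mr) if np.ndim(vo2_l_min) == 0 and np.ndim(rer) == 0 else mr


def energy_cost(rate_w: float, speed_ms: float, cond: TestConditions) -> float:
    """Energy cost of locomotion [J per kg system mass per metre].

    EC = MR / (v * m_sys). Undefined at rest.
    """
    if speed_ms <= 0.0:
        raise ValueError("energy cost is undefined at zero speed")
    return rate_w / (speed_ms * cond.system_mass_kg)


def gross_efficiency(power_w: float, rate_w: float) -> float:
    """Gross efficiency GE = power output / metabolic rate (fraction)."""
    if rate_w <= 0.0:
        raise ValueError("metabolic rate must be positive")
    return power_w / rate_w


def net_efficiency(power_w: float, rate_w: float, baseline_rate_w: float) -> float:
    """Net efficiency NE = power / (metabolic rate - baseline rate).

    The standing-baseline metabolic rate MR_BL is subtracted from the
    denominator, so NE >= GE for any positive baseline.
    """
    if rate_w <= baseline_rate_w:
        raise ValueError("metabolic rate must exceed the baseline rate")
    return power_w / (rate_w - baseline_rate_w)


def o2_equivalent(energy_j):
    """Convert metabolic energy [J] to an O2-equivalent volume [mL].

    Uses the RER = 1.00 Weir equivalence (0.047801 mL O2 per joule); negative
    energies are passed through, since accumulated deficits can be negative.
    """
    e = np.asarray(energy_j, dtype=float)
    out = e * O2_EQ_ML_PER_J
    return float(out) if np.ndim(energy_j) == 0 else out
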