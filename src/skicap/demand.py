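"""Speed -> metabolic-rate demand regressions and regression-derived efficiency.

Four per-athlete regressions underlie the MAOD (maximal accumulated oxygen
deficit) estimators: linear and second-degree polynomial fits of submaximal
metabolic rate (W per kg system mass) against treadmill speed (km/h), each
either with the standing-baseline metabolic rate appended as an extra data
point at speed zero ("+Y", baseline included) or fit to the stage points only
("-Y"). The intercept is always freely estimated, never forced through the
baseline. Extrapolating these fits to supramaximal time-trial speeds is the
MAOD demand estimate; the gap between a chord and a convex curve beyond the
fit range is exactly why linear and polynomial variants disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .energetics import KMH_TO_MS, TestConditions

__all__ = ["DemandModel", "fit_demand_model", "predict_demand", "ge_from_model", "delta_efficiency"]

ModelKind = Literal["linear", "quadratic"]


@dataclass(frozen=True)
class DemandModel:
    """A fitted speed -> metabolic-rate regression.

    Rates are W per kg system mass; speeds km/h. ``q_coeff`` is zero iff the
    model is linear. ``see`` is the standard error of the estimate computed
    with n - p residual degrees of freedom (p = number of fitted
    coefficients). ``fit_speeds`` records the training speed range so that
    extrapolation can be flagged downstream.
    """

    kind: ModelKind
    include_baseline: bool
    intercept: float
    l_coeff: float
    q_coeff: float
    r2: float
    see: float
    fit_speeds: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind == "linear" and self.q_coeff != 0.0:
            raise ValueError("linear model must have q_coeff = 0")
        if self.see < 0.0:
            raise ValueError("see must be >= 0")

    @property
    def fit_speed_range(self) -> tuple:
        return (min(self.fit_speeds), max(self.fit_speeds)) if self.fit_speeds else (np.nan, np.nan)

    def is_extrapolating(self, speed_kmh) -> np.ndarray:
        lo, hi = self.fit_speed_range
        v = np.asarray(speed_kmh, dtype=float)
        return (v < lo) | (v > hi)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "include_baseline": self.include_baseline,
            "intercept": self.intercept,
            "l_coeff": self.l_coeff,
            "q_coeff": self.q_coeff,
            "r2": self.r2,
            "see": self.see,
            "fit_speed_min": self.fit_speed_range[0],
            "fit_speed_max": self.fit_speed_range[1],
        }


def _ols(x: np.ndarray, y: np.ndarray, degree: int):
    """OLS polynomial fit returning (coefs ascending, r2, see)."""
    n = x.size
    p = degree + 1
    X = np.vander(x, p, increasing=True)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design: need distinct speeds")
    coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    dof = n - p
    if dof <= 0:
        raise ValueError("not enough points for residual degrees of freedom")
    see = float(np.sqrt(max(ss_res, 0.0) / dof))
    # clip tiny negative r2 from round-off on perfect fits
    return coefs, min(max(r2, 0.0), 1.0), see


def fit_demand_model(
    stages: Sequence[tuple],
    baseline_rate: Optional[float],
    kind: ModelKind,
    *,
    include_baseline: Optional[bool] = None,
) -> DemandModel:
    """Fit a linear or quadratic demand regression to submaximal stage data.

    Parameters
    ----------
    stages:
        Sequence of ``(speed_kmh, rate_w_per_kg)`` pairs, one per stage.
    baseline_rate:
        Standing-baseline metabolic rate (W/kg system mass). When given (and
        ``include_baseline`` is not explicitly False) it is appended to the
        fit data as an extra point at speed 0; the intercept remains freely
        estimated.
    kind:
        ``"linear"`` or ``"quadratic"`` (second degree).

    Raises
    ------
    ValueError
        For too few stages (< 3 linear, < 4 quadratic), duplicate speeds, or
        a baseline requested without a baseline value.
    """
    if include_baseline is None:
        include_baseline = baseline_rate is not None
    if include_baseline and baseline_rate is None:
        raise ValueError("include_baseline requires a baseline_rate")

    speeds = np.array([s for s, _ in stages], dtype=float)
    rates = np.array([r for _, r in stages], dtype=float)
    min_n = 3 if kind == "linear" else 4
    if speeds.size < min_n:
        raise ValueError(f"{kind} fit needs >= {min_n} stages, got {speeds.size}")
    if np.unique(speeds).size != speeds.size:
        raise ValueError("stage speeds must be distinct")

    x, y = speeds, rates
    if include_baseline:
        x = np.append(x, 0.0)
        y = np.append(y, float(baseline_rate))

    degree = 1 if kind == "linear" else 2
    coefs, r2, see = _ols(x, y, degree)
    intercept = float(coefs[0])
    l_coeff = float(coefs[1])
    q_coeff = float(coefs[2]) if degree == 2 else 0.0
    return DemandModel(
        kind=kind,
        include_baseline=include_baseline,
        intercept=intercept,
        l_coeff=l_coeff,
        q_coeff=q_coeff,
        r2=r2,
        see=see,
        fit_speeds=tuple(speeds.tolist()),
    )


def predict_demand(model: DemandModel, speed_kmh):
    """Evaluate the demand regression at a speed (km/h), scalar or array.

    Extrapolation beyond the fitted speed range is permitted — extrapolating
    to supramaximal speed is precisely how the MAOD demand is obtained — and
    can be detected via ``model.is_extrapolating``.
    """
    v = np.asarray(speed_kmh, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed_kmh must be >= 0")
    out = model.intercept + model.l_coeff * v + model.q_coeff * v**2
    return float(out) if np.ndim(speed_kmh) == 0 else out


def ge_from_model(model: DemandModel, speed_kmh, cond: TestConditions):
    """Regression-implied gross efficiency at a speed (fraction).

    GE_REG = (power output per kg system mass) / (predicted metabolic rate
    per kg system mass). For a linear model with zero intercept this ratio is
    the same at every speed (and equals the delta efficiency); a positive
    intercept makes it increase with speed, a negative one decrease.
    """
    rate = predict_demand(model, speed_kmh)
    if np.any(np.asarray(rate) <= 0):
        raise ValueError("predicted metabolic rate must be positive for GE")
    v_ms = np.asarray(speed_kmh, dtype=float) * KMH_TO_MS
    power_per_kg = v_ms * cond.power_per_kg_per_ms()
    out = power_per_kg / rate
    return float(out) if np.ndim(speed_kmh) == 0 else out


def delta_efficiency(
    points: Sequence[tuple],
    baseline_point: Optional[tuple] = None,
) -> float:
    """Delta efficiency: reciprocal slope of the rate-on-power OLS regression.

    ``points`` are ``(power, rate)`` pairs in any consistent units (the ratio
    is dimensionless); an optional ``(power, rate)`` baseline point may be
    appended, mirroring the "+Y" regression variant.
    """
    pts = list(points)
    if baseline_point is not None:
        pts = pts + [baseline_point]
    if len(pts) < 3:
        raise ValueError("delta efficiency needs >= 3 points")
    power = np.array([p for p, _ in pts], dtype=float)
    rate = np.array([r for _, r in pts], dtype=float)
    coefs, _, _ = _ols(power, rate, 1)
    slope = float(coefs[1])
    if abs(slope) < 1e-12 * max(1.0, float(np.max(np.abs(rate)))):
        raise ValueError("zero slope: delta efficiency undefined")
    return 1.0 / slope
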