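"""Accumulated O2-deficit estimation from a 4-min supramaximal time trial.

Given per-athlete submaximal stage data and a 1-Hz time-trial series of
speed, VO2 and RER, this module computes — for each of the six estimation
methods plus a lactate-based alternative — the required metabolic rate
during the trial, the instantaneous anaerobic rate (required minus aerobic),
and its time integral: the anaerobic capacity E_an (kJ/kg) and its
O2-equivalent, the accumulated O2 deficit (mL/kg).

Method identifiers follow the field's naming:

- ``8+Y_LIN`` / ``8-Y_LIN``: linear MAOD demand regression with the standing
  baseline included as a speed-0 point / excluded;
- ``8+Y_POL`` / ``8-Y_POL``: second-degree polynomial counterparts;
- ``GE_AVG`` / ``GE_LAST``: fixed gross efficiency from the mean of the eight
  stages / the last stage;
- ``LACTATE``: simplified alternative from the pre/post blood-lactate delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .demand import DemandModel, fit_demand_model, predict_demand
from .energetics import (
    KMH_TO_MS,
    O2_EQ_ML_PER_J,
    BaselineMeasurement,
    StageMeasurement,
    TestConditions,
    gross_efficiency,
    metabolic_rate_weir,
)

__all__ = [
    "MAOD_METHODS",
    "GE_METHODS",
    "ALL_METHODS",
    "TimeTrialSeries",
    "PeakVariables",
    "CapacityEstimate",
    "resample_to_1hz",
    "compute_peaks",
    "required_metabolic_rate",
    "anaerobic_rate_series",
    "integrate_anaerobic_capacity",
    "lactate_o2_deficit",
    "fit_all_demand_models",
    "estimate_all_methods",
]

MAOD_METHODS = ("8+Y_LIN", "8-Y_LIN", "8+Y_POL", "8-Y_POL")
GE_METHODS = ("GE_AVG", "GE_LAST")
ALL_METHODS = MAOD_METHODS + GE_METHODS


@dataclass
class TimeTrialSeries:
    """Aligned 1-Hz time-trial series (t in whole seconds, default 240 s)."""

    t: np.ndarray
    speed_kmh: np.ndarray
    vo2_l_min: np.ndarray
    rer: np.ndarray
    distance_m: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.speed_kmh = np.asarray(self.speed_kmh, dtype=float)
        self.vo2_l_min = np.asarray(self.vo2_l_min, dtype=float)
        self.rer = np.asarray(self.rer, dtype=float)
        n = self.t.size
        for name in ("speed_kmh", "vo2_l_min", "rer"):
            if getattr(self, name).size != n:
                raise ValueError(f"misaligned series: {name} has length "
                                 f"{getattr(self, name).size}, expected {n}")
        if n >= 2 and not np.allclose(np.diff(self.t), 1.0):
            raise ValueError("time-trial series must be uniformly sampled at 1 Hz")
        if np.any(self.speed_kmh < 0):
            raise ValueError("speeds must be >= 0")

    @property
    def duration_s(self) -> float:
        return float(self.t.size)  # one rectangle of 1 s per sample


@dataclass(frozen=True)
class PeakVariables:
    """Peak quantities extracted from the time trial.

    ``vo2peak`` is the highest 30-s moving average of VO2; ``rer_at_peak``
    the RER averaged over that same window; ``peak_aerobic_mr`` the Weir
    conversion of VO2peak at RER 1.00, per kg system mass.
    """

    vo2peak_l_min: float
    rer_at_peak: float
    peak_aerobic_mr_w_kg: float
    hr_peak_bpm: Optional[float] = None


@dataclass(frozen=True)
class CapacityEstimate:
    """Per-method anaerobic capacity summary for one athlete and trial."""

    method: str
    e_an_kj_kg: float
    o2_deficit_ml_kg: float
    mr_tt_req_mean_w_kg: Optional[float] = None
    mr_tt_req_pct_peak: Optional[float] = None
    ge_tt_avg: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "e_an_kj_kg": self.e_an_kj_kg,
            "o2_deficit_ml_kg": self.o2_deficit_ml_kg,
            "mr_tt_req_mean_w_kg": self.mr_tt_req_mean_w_kg,
            "mr_tt_req_pct_peak": self.mr_tt_req_pct_peak,
            "ge_tt_avg": self.ge_tt_avg,
        }


def resample_to_1hz(times_s, values) -> tuple:
    """Linearly interpolate irregularly sampled data onto integer seconds.

    Returns ``(t, v)`` with t the integer seconds spanning the input range.
    Device outputs logged at e.g. 2.46 Hz are brought to the 1-Hz grid all
    series computations assume.
    """
    t_in = np.asarray(times_s, dtype=float)
    v_in = np.asarray(values, dtype=float)
    if t_in.size < 2:
        raise ValueError("need >= 2 samples to resample")
    if np.any(np.diff(t_in) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    t_out = np.arange(np.ceil(t_in[0]), np.floor(t_in[-1]) + 1.0)
    return t_out, np.interp(t_out, t_in, v_in)


def compute_peaks(
    series: TimeTrialSeries,
    cond: TestConditions,
    hr_bpm: Optional[np.ndarray] = None,
    window_s: int = 30,
) -> PeakVariables:
    """Extract peak variables from the time trial.

    VO2peak is the maximum mean over any ``window_s`` consecutive 1-s
    samples; the RER at peak is averaged over the same window; peak heart
    rate is the highest single 1-s value. The peak aerobic metabolic rate
    converts VO2peak through the Weir equation at RER 1.00 (100% carbohydrate
    utilisation) and normalises by system mass.
    """
    n = series.t.size
    if n < window_s:
        raise ValueError(f"series shorter than the {window_s}-s window")
    kernel = np.ones(window_s) / window_s
    vo2_ma = np.convolve(series.vo2_l_min, kernel, mode="valid")
    i = int(np.argmax(vo2_ma))
    vo2peak = float(vo2_ma[i])
    rer_at_peak = float(series.rer[i : i + window_s].mean())
    peak_mr = metabolic_rate_weir(vo2peak, 1.00) / cond.system_mass_kg
    hr_peak = float(np.max(hr_bpm)) if hr_bpm is not None else None
    return PeakVariables(vo2peak, rer_at_peak, peak_mr, hr_peak)


def required_metabolic_rate(
    series: TimeTrialSeries,
    method: Union[DemandModel, float],
    cond: TestConditions,
) -> np.ndarray:
    """Per-second required metabolic rate MR_TT_req (W/kg system mass).

    For a MAOD method, the fitted demand regression is evaluated at each
    second's speed (extrapolation intended). For a GE method, ``method`` is
    the fixed gross-efficiency fraction and the instantaneous power output
    per kg is divided by it.
    """
    if isinstance(method, DemandModel):
        return predict_demand(method, series.speed_kmh)
    ge = float(method)
    if not (0.0 < ge < 1.0):
        raise ValueError(f"fixed GE must be in (0, 1), got {ge}")
    power_per_kg = series.speed_kmh * KMH_TO_MS * cond.power_per_kg_per_ms()
    return power_per_kg / ge


def aerobic_rate_series(
    series: TimeTrialSeries, cond: TestConditions, clamp_rer: bool = True
) -> np.ndarray:
    """Measured aerobic metabolic rate MR_ae (W/kg) at each second.

    RER is clamped to 1.00 by default: above the second ventilatory threshold
    the excess CO2 from bicarbonate buffering inflates RER beyond the
    substrate-utilisation range the Weir equation models.
    """
    rer = np.minimum(series.rer, 1.00) if clamp_rer else series.rer
    return metabolic_rate_weir(series.vo2_l_min, rer) / cond.system_mass_kg


def anaerobic_rate_series(
    mr_req: np.ndarray,
    series: TimeTrialSeries,
    cond: TestConditions,
    clamp_rer: bool = True,
) -> np.ndarray:
    """Instantaneous anaerobic rate MR_an,t = MR_req,t - MR_ae,t (W/kg).

    Negative values are retained: seconds where measured uptake exceeds the
    estimated requirement contribute negatively to the deficit.
    """
    mr_req = np.asarray(mr_req, dtype=float)
    if mr_req.size != series.t.size:
        raise ValueError("mr_req length does not match the time-trial series")
    return mr_req - aerobic_rate_series(series, cond, clamp_rer=clamp_rer)


def integrate_anaerobic_capacity(mr_an: np.ndarray) -> tuple:
    """Integrate the anaerobic rate series (1-Hz rectangle rule).

    Returns ``(e_an_kj_kg, o2_deficit_ml_kg)``: the anaerobic energy in
    kJ/kg and its O2 equivalent in mL/kg (0.047801 mL per joule).
    """
    e_an_j = float(np.sum(np.asarray(mr_an, dtype=float)) * 1.0)
    return e_an_j / 1000.0, e_an_j * O2_EQ_ML_PER_J


def lactate_o2_deficit(
    lactate_pre_mmol: float,
    lactate_post_mmol: float,
    ml_per_mmol: float = 3.0,
    lactic_fraction: float = 0.67,
) -> float:
    """Simplified lactate-based accumulated O2 deficit (mL/kg body mass).

    A 1 mmol/L rise in blood lactate across the trial is taken as equivalent
    to 3 mL/kg of O2 deficit from the lactic (glycolytic) source, which in
    turn covers ``lactic_fraction`` (default 67%) of the total deficit; the
    remainder is attributed to the alactic (phosphocreatine) source.
    A negative lactate delta yields a negative deficit, reported as-is.
    """
    if not (0.0 < lactic_fraction <= 1.0):
        raise ValueError("lactic_fraction must be in (0, 1]")
    return (lactate_post_mmol - lactate_pre_mmol) * ml_per_mmol / lactic_fraction


def fit_all_demand_models(
    stages: Sequence[StageMeasurement],
    baseline: BaselineMeasurement,
    cond: TestConditions,
) -> Dict[str, DemandModel]:
    """Fit the four MAOD demand regressions (rates per kg system mass)."""
    pts = [(s.speed_kmh, s.metabolic_rate_w() / cond.system_mass_kg) for s in stages]
    bl = baseline.metabolic_rate_w() / cond.system_mass_kg
    return {
        "8+Y_LIN": fit_demand_model(pts, bl, "linear", include_baseline=True),
        "8-Y_LIN": fit_demand_model(pts, None, "linear", include_baseline=False),
        "8+Y_POL": fit_demand_model(pts, bl, "quadratic", include_baseline=True),
        "8-Y_POL": fit_demand_model(pts, None, "quadratic", include_baseline=False),
    }


def stage_gross_efficiencies(
    stages: Sequence[StageMeasurement], cond: TestConditions
) -> np.ndarray:
    """Measured GE (fraction) at each submaximal stage."""
    return np.array(
        [gross_efficiency(s.power_w(cond), s.metabolic_rate_w()) for s in stages]
    )


def _summarise(
    method: str,
    mr_req: np.ndarray,
    series: TimeTrialSeries,
    cond: TestConditions,
    peak_mr: Optional[float],
    clamp_rer: bool,
) -> CapacityEstimate:
    mr_an = anaerobic_rate_series(mr_req, series, cond, clamp_rer=clamp_rer)
    e_an, deficit = integrate_anaerobic_capacity(mr_an)
    power_per_kg = series.speed_kmh * KMH_TO_MS * cond.power_per_kg_per_ms()
    with np.errstate(divide="ignore", invalid="ignore"):
        ge_t = np.where(mr_req > 0, power_per_kg / mr_req, np.nan)
    mean_req = float(np.mean(mr_req))
    return CapacityEstimate(
        method=method,
        e_an_kj_kg=e_an,
        o2_deficit_ml_kg=deficit,
        mr_tt_req_mean_w_kg=mean_req,
        mr_tt_req_pct_peak=100.0 * mean_req / peak_mr if peak_mr else None,
        ge_tt_avg=float(np.nanmean(ge_t)),
    )


def estimate_all_methods(
    stages: Sequence[StageMeasurement],
    baseline: BaselineMeasurement,
    series: TimeTrialSeries,
    cond: TestConditions,
    lactate_pre_mmol: Optional[float] = None,
    lactate_post_mmol: Optional[float] = None,
    clamp_rer: bool = True,
) -> Dict[str, CapacityEstimate]:
    """Run every estimator on one athlete's complete record.

    Returns a dict keyed by method id: the four MAOD regressions, the two
    fixed-GE methods, and — when pre/post lactates are supplied — the
    simplified lactate-based alternative (which carries only a deficit, no
    time-resolved requirement).
    """
    models = fit_all_demand_models(stages, baseline, cond)
    ge_stage = stage_gross_efficiencies(stages, cond)
    peaks = compute_peaks(series, cond)
    peak_mr = peaks.peak_aerobic_mr_w_kg

    out: Dict[str, CapacityEstimate] = {}
    for mid in MAOD_METHODS:
        mr_req = required_metabolic_rate(series, models[mid], cond)
        out[mid] = _summarise(mid, mr_req, series, cond, peak_mr, clamp_rer)
    for mid, ge in (("GE_AVG", float(ge_stage.mean())), ("GE_LAST", float(ge_stage[-1]))):
        mr_req = required_metabolic_rate(series, ge, cond)
        out[mid] = _summarise(mid, mr_req, series, cond, peak_mr, clamp_rer)
    if lactate_pre_mmol is not None and lactate_post_mmol is not None:
        deficit = lactate_o2_deficit(lactate_pre_mmol, lactate_post_mmol)
        out["LACTATE"] = CapacityEstimate(
            method="LACTATE",
            e_an_kj_kg=deficit / O2_EQ_ML_PER_J / 1000.0,
            o2_deficit_ml_kg=deficit,
        )
    return out
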