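"""CSV input/output and the frame-level pipeline driver.

One tabular dialect throughout: comma-separated, UTF-8, header row, period
decimal separator. Units are declared in the column names (speeds km/h, VO2
L/min, masses kg, rates W/kg). Files written by this package start with a
``#`` comment block recording the package version, seed, configuration hash
and library versions; readers skip those lines.

Tables
------
stages.csv    athlete_id, stage, speed_kmh, vo2_l_min, rer, hr_bpm
athletes.csv  athlete_id, incline_deg, mu_r, body_mass_kg, system_mass_kg,
              baseline_vo2_l_min, baseline_rer,
              lactate_pre_mmol, lactate_post_mmol (optional)
tt.csv        athlete_id, t_s, speed_kmh, vo2_l_min, rer
truth.csv     athlete_id, tt_speed_kmh, true_e_an_kj_kg,
              true_o2_deficit_ml_kg, aerobic_ceiling_w_kg (simulated only)
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .energetics import BaselineMeasurement, StageMeasurement, TestConditions
from .simulate import Cohort
from .timetrial import TimeTrialSeries, estimate_all_methods, fit_all_demand_models
from .demand import delta_efficiency, ge_from_model
from .energetics import gross_efficiency

logger = logging.getLogger("skicap")

STAGE_COLUMNS = ["athlete_id", "stage", "speed_kmh", "vo2_l_min", "rer", "hr_bpm"]
TT_COLUMNS = ["athlete_id", "t_s", "speed_kmh", "vo2_l_min", "rer"]
ATHLETE_COLUMNS = [
    "athlete_id", "incline_deg", "mu_r", "body_mass_kg", "system_mass_kg",
    "baseline_vo2_l_min", "baseline_rer",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_block(seed: Optional[int], config: Optional[dict]) -> str:
    import skicap

    parts = [f"skicap v{skicap.__version__}", f"numpy={np.__version__}", f"pandas={pd.__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return "# " + " | ".join(parts) + "\n"


def write_csv(df: pd.DataFrame, path, seed: Optional[int] = None, config: Optional[dict] = None) -> None:
    """Write a DataFrame with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_block(seed, config))
        df.to_csv(fh, index=False, float_format="%.10g")


def read_csv(path, required: Optional[List[str]] = None) -> pd.DataFrame:
    """Read a CSV written by this package (or compatible), checking columns."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # surface the offending line
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Cohort <-> frames
# ---------------------------------------------------------------------------

def cohort_to_frames(cohort: Cohort) -> Dict[str, pd.DataFrame]:
    """Flatten a simulated cohort into the four standard tables."""
    stage_rows, tt_rows, ath_rows, truth_rows = [], [], [], []
    for a in cohort:
        for i, s in enumerate(a.stages, start=1):
            stage_rows.append({
                "athlete_id": a.athlete_id, "stage": i, "speed_kmh": s.speed_kmh,
                "vo2_l_min": s.vo2_l_min, "rer": s.rer, "hr_bpm": s.hr_bpm,
            })
        tt_rows.append(pd.DataFrame({
            "athlete_id": a.athlete_id, "t_s": a.tt.t.astype(int),
            "speed_kmh": a.tt.speed_kmh, "vo2_l_min": a.tt.vo2_l_min, "rer": a.tt.rer,
        }))
        ath_rows.append({
            "athlete_id": a.athlete_id,
            "incline_deg": a.conditions.incline_deg,
            "mu_r": a.conditions.mu_r,
            "body_mass_kg": a.conditions.body_mass_kg,
            "system_mass_kg": a.conditions.system_mass_kg,
            "baseline_vo2_l_min": a.baseline.vo2_l_min,
            "baseline_rer": a.baseline.rer,
            "lactate_pre_mmol": a.lactate_pre_mmol,
            "lactate_post_mmol": a.lactate_post_mmol,
        })
        truth_rows.append({"athlete_id": a.athlete_id, **a.truth})
    return {
        "stages": pd.DataFrame(stage_rows),
        "tt": pd.concat(tt_rows, ignore_index=True),
        "athletes": pd.DataFrame(ath_rows),
        "truth": pd.DataFrame(truth_rows),
    }


def _athlete_inputs(aid: str, stages_df: pd.DataFrame, tt_df: pd.DataFrame, ath_row: pd.Series):
    cond = TestConditions(
        incline_deg=float(ath_row["incline_deg"]),
        mu_r=float(ath_row["mu_r"]),
        body_mass_kg=float(ath_row["body_mass_kg"]),
        system_mass_kg=float(ath_row["system_mass_kg"]),
    )
    if pd.isna(ath_row.get("baseline_vo2_l_min")):
        raise ValueError(f"missing baseline measurement for athlete {aid}")
    baseline = BaselineMeasurement(
        vo2_l_min=float(ath_row["baseline_vo2_l_min"]), rer=float(ath_row["baseline_rer"])
    )
    sub = stages_df[stages_df["athlete_id"] == aid].sort_values("stage")
    stages = [
        StageMeasurement(
            speed_kmh=float(r.speed_kmh), vo2_l_min=float(r.vo2_l_min), rer=float(r.rer),
            hr_bpm=None if "hr_bpm" not in sub.columns or pd.isna(r.hr_bpm) else float(r.hr_bpm),
        )
        for r in sub.itertuples()
    ]
    tts = tt_df[tt_df["athlete_id"] == aid].sort_values("t_s")
    series = None
    if len(tts):
        series = TimeTrialSeries(
            t=tts["t_s"].to_numpy(float),
            speed_kmh=tts["speed_kmh"].to_numpy(float),
            vo2_l_min=tts["vo2_l_min"].to_numpy(float),
            rer=tts["rer"].to_numpy(float),
        )
    return cond, baseline, stages, series


def _check_ids(stages_df: pd.DataFrame, tt_df: pd.DataFrame, athletes_df: pd.DataFrame) -> List[str]:
    ids_s = set(stages_df["athlete_id"])
    ids_t = set(tt_df["athlete_id"])
    ids_a = set(athletes_df["athlete_id"])
    unmatched = (ids_s ^ ids_a) | (ids_t - ids_a)
    if unmatched:
        raise ValueError(f"unmatched athlete ids across files: {sorted(unmatched)}")
    return sorted(ids_a)


def fit_cohort_frames(
    stages_df: pd.DataFrame, athletes_df: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the four demand regressions per athlete.

    Returns ``(models, ge_reg)``: one row per athlete x regression variant
    with coefficients, r^2, SEE and (for the linear variants) the delta
    efficiency; and a per-stage table of regression-implied vs measured GE.
    """
    model_rows, ge_rows = [], []
    for aid in sorted(set(stages_df["athlete_id"])):
        row = athletes_df[athletes_df["athlete_id"] == aid]
        if row.empty:
            raise ValueError(f"athlete {aid} present in stages but not in athletes table")
        cond, baseline, stages, _ = _athlete_inputs(aid, stages_df, stages_df.iloc[0:0].assign(t_s=[]), row.iloc[0])
        models = fit_all_demand_models(stages, baseline, cond)
        pts = [(s.power_w(cond) / cond.system_mass_kg, s.metabolic_rate_w() / cond.system_mass_kg) for s in stages]
        bl_pt = (0.0, baseline.metabolic_rate_w() / cond.system_mass_kg)
        for mid, model in models.items():
            d = {"athlete_id": aid, "method": mid, **model.to_dict()}
            if model.kind == "linear":
                d["delta_efficiency"] = delta_efficiency(pts, bl_pt if model.include_baseline else None)
            else:
                d["delta_efficiency"] = np.nan
            model_rows.append(d)
            for i, s in enumerate(stages, start=1):
                ge_rows.append({
                    "athlete_id": aid, "method": mid, "stage": i, "speed_kmh": s.speed_kmh,
                    "ge_reg": ge_from_model(model, s.speed_kmh, cond),
                    "ge_measured": gross_efficiency(s.power_w(cond), s.metabolic_rate_w()),
                })
    return pd.DataFrame(model_rows), pd.DataFrame(ge_rows)


def estimate_cohort_frames(
    stages_df: pd.DataFrame,
    tt_df: pd.DataFrame,
    athletes_df: pd.DataFrame,
    clamp_rer: bool = True,
    basis: str = "system",
) -> pd.DataFrame:
    """Run all estimators per athlete; one tidy row per athlete x method.

    ``basis`` selects the per-kg normalisation of energies and rates:
    ``"system"`` (athlete + equipment, default) or ``"body"``. The
    lactate-based estimate is inherently per kg body mass and is rescaled to
    the system basis when that basis is requested.
    """
    if basis not in ("system", "body"):
        raise ValueError("basis must be 'system' or 'body'")
    ids = _check_ids(stages_df, tt_df, athletes_df)
    rows = []
    for aid in ids:
        ath = athletes_df[athletes_df["athlete_id"] == aid].iloc[0]
        cond, baseline, stages, series = _athlete_inputs(aid, stages_df, tt_df, ath)
        if series is None:
            raise ValueError(f"no time-trial data for athlete {aid}")
        lac_pre = ath.get("lactate_pre_mmol")
        lac_post = ath.get("lactate_post_mmol")
        if pd.isna(lac_pre) or pd.isna(lac_post):
            logger.warning("athlete %s: lactates absent, skipping the lactate method", aid)
            lac_pre = lac_post = None
        est = estimate_all_methods(
            stages, baseline, series, cond,
            lactate_pre_mmol=None if lac_pre is None else float(lac_pre),
            lactate_post_mmol=None if lac_post is None else float(lac_post),
            clamp_rer=clamp_rer,
        )
        scale_sys_to_body = cond.system_mass_kg / cond.body_mass_kg
        for mid, e in est.items():
            d = e.to_dict()
            if mid == "LACTATE":
                if basis == "system":
                    d["e_an_kj_kg"] /= scale_sys_to_body
                    d["o2_deficit_ml_kg"] /= scale_sys_to_body
            elif basis == "body":
                for key in ("e_an_kj_kg", "o2_deficit_ml_kg", "mr_tt_req_mean_w_kg"):
                    if d[key] is not None:
                        d[key] *= scale_sys_to_body
            rows.append({"athlete_id": aid, "basis": basis, **d})
    return pd.DataFrame(rows)
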