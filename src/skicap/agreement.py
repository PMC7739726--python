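"""Method-agreement statistics for paired anaerobic-capacity estimates.

Bland–Altman mean difference with 95% limits of agreement, the typical
(within-pair) error SD(diff)/sqrt(2), Hedges' g_av standardised mean
difference with small-sample correction, RMSE, and within-athlete CV.
Sample statistics use the n-1 divisor throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethodComparison",
    "bland_altman",
    "typical_error",
    "hedges_g_av",
    "rmse",
    "within_athlete_cv",
    "pairwise_comparisons",
]


@dataclass(frozen=True)
class MethodComparison:
    """Pairwise agreement summary between two methods (differences a - b)."""

    method_a: str
    method_b: str
    n: int
    mean_diff: float
    loa_low: float
    loa_high: float
    typical_error: float
    effect_size: Optional[float]
    p_value: float

    def to_dict(self) -> dict:
        return {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "typical_error": self.typical_error,
            "effect_size": self.effect_size,
            "p_value": self.p_value,
        }


def _paired(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    return a, b


def bland_altman(a, b, method_a: str = "a", method_b: str = "b") -> MethodComparison:
    """Bland–Altman agreement between two paired series.

    Differences are a - b; limits of agreement are mean ± 1.96·SD of the
    differences; the mean difference is tested against zero with a two-sided
    one-sample t-test.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        # identical differences: the t statistic is degenerate; p is 1 for a
        # zero mean difference and 0 otherwise
        p = 1.0 if mean_d == 0.0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    try:
        es = hedges_g_av(a, b)
    except ValueError:
        es = None
    return MethodComparison(
        method_a=method_a,
        method_b=method_b,
        n=n,
        mean_diff=mean_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        typical_error=sd_d / np.sqrt(2.0),
        effect_size=es,
        p_value=p,
    )


def typical_error(a, b) -> float:
    """Typical error: SD of the pairwise differences divided by sqrt(2).

    Under the classical measurement model where each method adds independent
    noise of equal variance, this is the within-method error SD.
    """
    a, b = _paired(a, b)
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    return float((a - b).std(ddof=1) / np.sqrt(2.0))


def hedges_g_av(a, b) -> float:
    """Hedges' g_av for a paired design.

    mean(a - b) standardised by the average-SD standardiser
    sqrt((SD(a)^2 + SD(b)^2)/2), multiplied by the small-sample bias
    correction 1 - 3/(4(n-1) - 1).
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 3:
        raise ValueError("need >= 3 pairs")
    sd_av = np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0)
    if sd_av == 0.0:
        raise ValueError("zero pooled SD: effect size undefined")
    correction = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return float((a - b).mean() / sd_av * correction)


def rmse(a, b) -> float:
    """Root mean square error between two aligned series."""
    a, b = _paired(a, b)
    if a.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def within_athlete_cv(values) -> float:
    """Within-athlete coefficient of variation, percent: 100·SD/mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / m)


def pairwise_comparisons(estimates: pd.DataFrame, value_col: str = "o2_deficit_ml_kg") -> pd.DataFrame:
    """All pairwise method comparisons from a tidy athlete x method table.

    ``estimates`` needs columns ``athlete_id``, ``method`` and ``value_col``.
    Methods are compared in their order of first appearance; with the six
    standard estimators this yields the 15 pairs of the usual agreement grid.
    """
    wide = estimates.pivot(index="athlete_id", columns="method", values=value_col)
    methods = [m for m in estimates["method"].unique() if m in wide.columns]
    if len(methods) < 2:
        raise ValueError("need >= 2 methods to compare")
    rows = []
    for ma, mb in combinations(methods, 2):
        sub = wide[[ma, mb]].dropna()
        rows.append(bland_altman(sub[ma].to_numpy(), sub[mb].to_numpy(), ma, mb).to_dict())
    return pd.DataFrame(rows)
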