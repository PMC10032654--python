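"""Statistical comparisons for paired swimming-condition experiments.

Welch t-tests (unequal variances, Satterthwaite degrees of freedom) with
explicit one-sided directions, ordinary least-squares regression with
R^2 for the phase-difference-versus-distance relationship, and a
per-group condition report of kinematic summaries.

The Welch test is applied to the two condition samples even when trials
are paired, matching the study design it mirrors; a classical paired
t-test is available alongside it for paired samples.  The one-sided
direction is always an explicit argument and never inferred from the
data, and no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "RegressionResult",
    "welch_t",
    "paired_t",
    "linear_fit",
    "condition_report",
]

Alternative = Literal["less", "greater", "two_sided"]

_SCIPY_ALT = {"less": "less", "greater": "greater", "two_sided": "two-sided"}


@dataclass(frozen=True)
class StatsResult:
    t: float
    df: float
    p: float
    alternative: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if not self.df > 0:
            raise ValueError("degrees of freedom must be positive")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 outside [0, 1]")


def _check_samples(a: np.ndarray, b: np.ndarray) -> None:
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both samples have zero variance; t undefined")


def welch_t(a, b, alternative: Alternative = "two_sided") -> StatsResult:
    """Welch's unequal-variance t-test of mean(a) against mean(b).

    ``alternative="less"`` tests whether mean(a) < mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_samples(a, b)
    if alternative not in _SCIPY_ALT:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = sps.ttest_ind(a, b, equal_var=False, alternative=_SCIPY_ALT[alternative])
    return StatsResult(float(res.statistic), float(res.df), float(res.pvalue), alternative)


def paired_t(a, b, alternative: Alternative = "two_sided") -> StatsResult:
    """Classical paired t-test on matched observations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    _check_samples(a, b)
    if np.var(a - b, ddof=1) == 0.0:
        raise ValueError("zero-variance differences; paired t undefined")
    res = sps.ttest_rel(a, b, alternative=_SCIPY_ALT[alternative])
    return StatsResult(float(res.statistic), float(a.size - 1), float(res.pvalue),
                       alternative)


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least-squares line with R^2 = 1 - SS_res / SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0.0:
        return RegressionResult(0.0, float(y.mean()), 0.0)
    res = sps.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue**2))


_METRIC_TESTS = {
    # metric -> (one-sided direction of the hypothesised change, test sidedness)
    "frequency_hz": "less",
    "delta_phi_rad": "less",
    "amplitude_m": "two_sided",
}


def condition_report(trials: pd.DataFrame, baseline: str, treatment: str,
                     id_col: str = "individual", condition_col: str = "condition",
                     group_col: str | None = "size_group",
                     metrics: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-group summary of paired condition comparisons.

    ``trials`` holds one row per individual and condition with metric
    columns (by default tail-beat frequency, overall phase lag and tail
    amplitude).  Individuals missing either condition are excluded with
    a warning.  For each group and metric the report lists the mean and
    s.d. under both conditions, the percent change from baseline to
    treatment, and the Welch test of the hypothesised direction
    (frequency and phase lag decrease: one-sided 'less'; amplitude:
    two-sided), plus the classical paired t-test p-value.
    """
    metrics = dict(_METRIC_TESTS) if metrics is None else metrics
    df = trials.copy()
    if group_col is None:
        group_col = "_group"
        df[group_col] = "all"
    counts = df.groupby(id_col)[condition_col].nunique()
    unpaired = counts[counts < 2].index.tolist()
    if unpaired:
        warnings.warn(
            f"excluding unpaired individuals (missing a condition): {unpaired}",
            stacklevel=2,
        )
        df = df[~df[id_col].isin(unpaired)]
    if df.empty:
        raise ValueError("no paired individuals left to compare")

    rows = []
    for group, sub in df.groupby(group_col, sort=False):
        means = sub.groupby([id_col, condition_col]).mean(numeric_only=True)
        for metric, alternative in metrics.items():
            if metric not in sub.columns:
                continue
            base = means.xs(baseline, level=condition_col)[metric]
            treat = means.xs(treatment, level=condition_col)[metric]
            common = base.index.intersection(treat.index)
            base, treat = base[common].to_numpy(), treat[common].to_numpy()
            pct = float((treat.mean() - base.mean()) / base.mean() * 100.0)
            try:
                welch = welch_t(treat, base, alternative=alternative)
                t_stat, df_w, p_w = welch.t, welch.df, welch.p
            except ValueError:
                # identical zero-variance conditions: no evidence either way
                t_stat, df_w = 0.0, float(len(base) - 1)
                p_w = 0.5 if alternative in ("less", "greater") else 1.0
            try:
                p_paired = paired_t(treat, base, alternative=alternative).p
            except ValueError:
                p_paired = 0.5 if alternative in ("less", "greater") else 1.0
            rows.append({
                group_col: group,
                "metric": metric,
                "n": int(len(base)),
                f"mean_{baseline}": float(base.mean()),
                f"sd_{baseline}": float(base.std(ddof=1)) if len(base) > 1 else 0.0,
                f"mean_{treatment}": float(treat.mean()),
                f"sd_{treatment}": float(treat.std(ddof=1)) if len(treat) > 1 else 0.0,
                "percent_change": pct,
                "alternative": alternative,
                "welch_t": t_stat,
                "welch_df": df_w,
                "welch_p": p_w,
                "paired_p": p_paired,
            })
    return pd.DataFrame(rows)
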