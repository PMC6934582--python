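"""Reaction-time distribution analysis.

Saccadic reaction times are summarised two ways: Kaplan-Meier survivor
curves S(t) — the proportion of trials on which no saccade has yet occurred
by time t — with product-limit medians and log-log (exponential-Greenwood)
median confidence intervals; and a Welch two-sample t test on log reaction
time comparing error and correct trials (latency distributions are
right-skewed, so the log scale symmetrises them). All analysed latencies lie
inside the 80-700 ms acceptance window, so censoring is structurally absent,
but the estimator accepts censor flags for generality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .records import ERROR_OUTCOMES, GROUPS, OUTCOME_EXCLUDED


@dataclass
class KMCurve:
    """Product-limit survivor curve with median and 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    median_ci: tuple
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(latencies, censor_flags=None, label: str = "") -> KMCurve:
    """Kaplan-Meier curve of saccade latencies.

    ``censor_flags`` marks right-censored observations (True = censored);
    omitted means every latency is an observed event. The median is the
    smallest time with S(t) <= 0.5; its CI uses the log(-log) transform.
    """
    latencies = np.asarray(latencies, dtype=float)
    if latencies.size == 0:
        raise ValueError("empty latency vector")
    if np.any(latencies <= 0):
        raise ValueError("latencies must be positive")
    observed = (np.ones_like(latencies, dtype=bool) if censor_flags is None
                else ~np.asarray(censor_flags, dtype=bool))
    kmf = KaplanMeierFitter(label=label or "KM")
    kmf.fit(latencies, event_observed=observed)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    times = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].to_numpy(float)
    return KMCurve(
        times=times, survival=surv, at_risk=at_risk,
        median=float(kmf.median_survival_time_), median_ci=(lo, hi),
        n=int(latencies.size),
    )


def welch_log_rt(correct_latencies, error_latencies) -> dict:
    """Welch two-sample t test on natural-log reaction times.

    Returns t, Welch-Satterthwaite df, two-sided p, pooled-SD Cohen's d on
    the log scale, and the variance-explained identity
    r_squared = t^2 / (t^2 + df).
    """
    a = np.asarray(error_latencies, dtype=float)
    b = np.asarray(correct_latencies, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("latencies must be positive")
    la, lb = np.log(a), np.log(b)
    res = stats.ttest_ind(la, lb, equal_var=False)
    t, df = float(res.statistic), float(res.df)
    sp = math.sqrt(((a.size - 1) * la.var(ddof=1) + (b.size - 1) * lb.var(ddof=1))
                   / (a.size + b.size - 2))
    d = (la.mean() - lb.mean()) / sp
    return {
        "t": t,
        "df": df,
        "p": float(res.pvalue),
        "cohen_d": float(d),
        "r_squared": r_squared_from_t(t, df),
    }


def r_squared_from_t(t: float, df: float) -> float:
    """Variance explained by a two-group contrast: t^2 / (t^2 + df)."""
    return float(t * t / (t * t + df))


def make_table5(df: pd.DataFrame) -> pd.DataFrame:
    """Median latency and 95% CI per group x initial-event type (correct vs
    error, irrespective of correction)."""
    d = df[df["outcome"] != OUTCOME_EXCLUDED].copy()
    d["event"] = np.where(d["outcome"].isin(ERROR_OUTCOMES), "error", "correct")
    rows = []
    for event in ("correct", "error"):
        for group in GROUPS:
            lat = d.loc[(d["group"] == group) & (d["event"] == event),
                        "latency_ms"].to_numpy(float)
            if lat.size == 0:
                continue
            curve = km_curve(lat, label=f"{group}/{event}")
            rows.append({
                "initial_event": event,
                "group": group,
                "n_trials": curve.n,
                "median_ms": curve.median,
                "ci_low_ms": curve.median_ci[0],
                "ci_high_ms": curve.median_ci[1],
            })
    return pd.DataFrame(rows)


def km_step_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Per-curve step functions (group x event) for plotting."""
    d = df[df["outcome"] != OUTCOME_EXCLUDED].copy()
    d["event"] = np.where(d["outcome"].isin(ERROR_OUTCOMES), "error", "correct")
    frames = []
    for (group, event), sub in d.groupby(["group", "event"]):
        curve = km_curve(sub["latency_ms"].to_numpy(float))
        frames.append(pd.DataFrame({
            "group": group, "initial_event": event,
            "t_ms": curve.times, "survival": curve.survival,
        }))
    return pd.concat(frames, ignore_index=True)
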