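"""Trial-history conditioning statistics for antisaccade sequences.

Every current trial (from the second usable trial onward) is attributed to a
stratum defined by what happened immediately before it: either the previous
trial's outcome category (correct / corrected error / uncorrected error) or
the run length of identical binarized outcomes ending at the previous trial.
Current-trial outcomes are binarized error vs correct — corrected and
uncorrected errors both count as errors on the *current* side. Excluded
trials are dropped before any pairing, and each participant's first usable
trial conditions nothing.

The module also carries the contingency machinery these tables need:
log-odds ratios with reciprocal-cell-count standard errors and Wald Z tests,
one-sample proportion Z tests (variance evaluated at the observed
proportion), Pearson chi-squared with Cramer's V, and inversion of printed
(error count, rounded proportion) pairs back to cell totals so published
tables can be re-analysed without raw data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import ERROR_OUTCOMES, GROUPS, OUTCOME_EXCLUDED

log = logging.getLogger(__name__)

PREV_CONDITIONS = ("prev_error_uncorrected", "prev_error_corrected", "prev_correct")
RUN_LENGTH_BINS = ("1", "2", "3", "4", "5", "6+")

#: Published previous-trial conditioning results from the motivating AD/MCI
#: antisaccade study: error counts on the current trial and the printed
#: (3-digit) error proportions, by group x previous-trial outcome. Totals are
#: not published; reconstruct_total() inverts these pairs.
PUBLISHED_PREVIOUS_TRIAL_COUNTS = {
    ("control", "prev_error_uncorrected"): (78, 0.595),
    ("control", "prev_error_corrected"): (362, 0.574),
    ("control", "prev_correct"): (319, 0.234),
    ("MCI", "prev_error_uncorrected"): (141, 0.758),
    ("MCI", "prev_error_corrected"): (374, 0.625),
    ("MCI", "prev_correct"): (260, 0.389),
    ("AD", "prev_error_uncorrected"): (123, 0.815),
    ("AD", "prev_error_corrected"): (262, 0.686),
    ("AD", "prev_correct"): (140, 0.335),
}


@dataclass(frozen=True)
class LogOddsEstimate:
    """A log-odds (or log-odds-ratio, or proportion-difference) estimate with
    its Wald standard error, Z statistic and p-value."""

    estimate: float
    se: float
    z: float
    p: float
    tails: str  # "one" | "two"
    comparison: str = ""


def _wald_p(z: float, tails: str) -> float:
    if tails == "two":
        return float(2.0 * stats.norm.sf(abs(z)))
    if tails == "one":
        return float(stats.norm.sf(abs(z)))
    raise ValueError("tails must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# sequence preparation
# ---------------------------------------------------------------------------

def usable_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Drop excluded trials and add a binarized ``is_error`` column; order by
    participant and trial index."""
    out = df[df["outcome"] != OUTCOME_EXCLUDED].copy()
    out["is_error"] = out["outcome"].isin(ERROR_OUTCOMES)
    return out.sort_values(["participant_id", "trial_index"], kind="stable")


def add_history_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Attach trial-history covariates to a trial-level table.

    Adds, per usable trial: ``prev_outcome`` (the previous usable trial's
    outcome category; missing on each participant's first usable trial),
    ``n_prev_success`` and ``n_prev_fail`` (mutually exclusive run lengths of
    immediately preceding consecutive correct / error trials; both 0 on the
    first trial). Excluded trials are dropped.
    """
    out = usable_trials(df)
    prev_outcome, n_succ, n_fail = [], [], []
    for _, sub in out.groupby("participant_id", sort=False):
        errs = sub["is_error"].to_list()
        outcomes = sub["outcome"].to_list()
        rs = rf = 0
        for j in range(len(errs)):
            prev_outcome.append(None if j == 0 else f"prev_{outcomes[j - 1]}")
            n_succ.append(rs)
            n_fail.append(rf)
            if errs[j]:
                rf += 1
                rs = 0
            else:
                rs += 1
                rf = 0
    out["prev_outcome"] = prev_outcome
    out["n_prev_success"] = n_succ
    out["n_prev_fail"] = n_fail
    return out


# ---------------------------------------------------------------------------
# conditioning tables
# ---------------------------------------------------------------------------

def condition_on_previous(df: pd.DataFrame) -> pd.DataFrame:
    """Error/total counts per (group, previous-trial outcome).

    Each usable trial j >= 2 contributes to the stratum of trial j-1's
    outcome; first trials contribute nowhere. Participants with fewer than
    two usable trials contribute nothing (logged).
    """
    cov = add_history_covariates(df)
    few = cov.groupby("participant_id").size()
    for pid in few[few < 2].index:
        log.info("participant %s has < 2 usable trials; skipped", pid)
    cur = cov[cov["prev_outcome"].notna()]
    rows = []
    for group in GROUPS:
        sub = cur[cur["group"] == group]
        for cond in PREV_CONDITIONS:
            cell = sub[sub["prev_outcome"] == cond]
            rows.append((group, cond, int(cell["is_error"].sum()), len(cell)))
    return pd.DataFrame(rows, columns=["group", "condition", "errors", "total"])


def run_lengths(df: pd.DataFrame) -> pd.DataFrame:
    """Error/total counts per (group, run type, run-length bin).

    For each usable trial j >= 2 the maximal run of identical binarized
    outcomes ending at trial j-1 defines the stratum; lengths >= 6 pool into
    the ``6+`` bin.
    """
    cov = add_history_covariates(df)
    cur = cov[(cov["n_prev_success"] > 0) | (cov["n_prev_fail"] > 0)]
    rows = []
    for group in GROUPS:
        sub = cur[cur["group"] == group]
        for run_type, col in (("correct", "n_prev_success"), ("error", "n_prev_fail")):
            runs = sub[sub[col] > 0]
            binned = np.minimum(runs[col], 6)
            for length, label in zip(range(1, 7), RUN_LENGTH_BINS):
                cell = runs[binned == length]
                rows.append(
                    (group, run_type, label, int(cell["is_error"].sum()), len(cell))
                )
    return pd.DataFrame(
        rows, columns=["group", "run_type", "length", "errors", "total"]
    )


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------

def reconstruct_total(errors: int, proportion: float) -> int:
    """Invert a printed (error count, 3-digit proportion) pair to the cell
    total.

    Returns the n nearest ``round(errors/proportion)`` for which
    ``errors/n`` reproduces the printed proportion at its printed precision;
    if no n within +-2 does, the closest candidate is returned with a
    warning. Note that for very large totals several n can print identically
    and the inversion is then correct only to that equivalence class.
    """
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must lie strictly between 0 and 1")
    if errors < 0:
        raise ValueError("errors must be nonnegative")
    n0 = round(errors / proportion)
    candidates = sorted(
        (n for n in range(n0 - 2, n0 + 3) if n >= max(errors, 1)),
        key=lambda n: (abs(errors / n - proportion), abs(n - n0)),
    )
    consistent = [n for n in candidates if abs(errors / n - proportion) <= 5e-4]
    if consistent:
        return int(consistent[0])
    best = candidates[0]
    warnings.warn(
        f"no total within {n0}+-2 reproduces proportion {proportion:.3f} "
        f"for {errors} errors; returning closest ({best})"
    )
    return int(best)


def proportion_se(errors: int, total: int) -> float:
    """Binomial standard error sqrt(p(1-p)/n) at the observed proportion."""
    if total <= 0:
        raise ValueError("total must be positive")
    p = errors / total
    return math.sqrt(p * (1.0 - p) / total)


def log_odds_ratio(a: int, b: int, c: int, d: int, tails: str = "two",
                   comparison: str = "") -> LogOddsEstimate:
    """Log-odds ratio ln(a/b) - ln(c/d) with SE sqrt(1/a+1/b+1/c+1/d).

    ``a`` errors vs ``b`` non-errors in condition 1; ``c``, ``d`` likewise in
    condition 2. Any zero cell triggers the Haldane-Anscombe +0.5 continuity
    correction (applied to all four cells) with a warning.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative")
    if any(x == 0 for x in cells):
        warnings.warn("zero cell: applying Haldane-Anscombe +0.5 correction")
        a, b, c, d = (x + 0.5 for x in cells)
    estimate = math.log(a / b) - math.log(c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = estimate / se
    return LogOddsEstimate(estimate, se, z, _wald_p(z, tails), tails, comparison)


def wald_one_sample(p_hat: float, n: int, p0: float = 0.5, tails: str = "one",
                    variance: str = "observed",
                    comparison: str = "") -> LogOddsEstimate:
    """One-sample proportion Z test.

    By default the variance is evaluated at the *observed* proportion,
    z = (p_hat - p0) / sqrt(p_hat (1 - p_hat) / n); set
    ``variance='null'`` for the p0-variance variant.
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError("p_hat must lie strictly between 0 and 1")
    if n <= 0:
        raise ValueError("n must be positive")
    if variance == "observed":
        se = math.sqrt(p_hat * (1.0 - p_hat) / n)
    elif variance == "null":
        se = math.sqrt(p0 * (1.0 - p0) / n)
    else:
        raise ValueError("variance must be 'observed' or 'null'")
    z = (p_hat - p0) / se
    return LogOddsEstimate(p_hat - p0, se, z, _wald_p(z, tails), tails, comparison)


def chisq_independence(table) -> tuple[float, int, float, float]:
    """Pearson chi-squared test of independence on an r x c count table,
    with Cramer's V = sqrt(chi2 / (N (min(r, c) - 1)))."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2 or table.sum() == 0:
        raise ValueError("need an r x c table with r, c >= 2 and positive total")
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("all expected counts must be positive")
    n = table.sum()
    k = min(table.shape) - 1
    v = math.sqrt(res.statistic / (n * k)) if res.statistic > 0 else 0.0
    return float(res.statistic), int(res.dof), float(res.pvalue), v


# ---------------------------------------------------------------------------
# published-style tables
# ---------------------------------------------------------------------------

def make_table2(df: pd.DataFrame) -> pd.DataFrame:
    """Previous-trial conditioning table: per group x previous-outcome cell,
    error count, total, proportion and SE; log-odds ratio of each patient
    group vs control within the condition; and the within-group uncorrected-
    vs-corrected previous-error contrast."""
    counts = condition_on_previous(df).set_index(["group", "condition"])

    def cell(group, cond):
        row = counts.loc[(group, cond)]
        return int(row["errors"]), int(row["total"])

    rows = []
    for cond in PREV_CONDITIONS:
        e_ctrl, n_ctrl = cell("control", cond)
        for group in GROUPS:
            e, n = cell(group, cond)
            lor = (
                log_odds_ratio(e, n - e, e_ctrl, n_ctrl - e_ctrl,
                               comparison=f"{group} vs control | {cond}")
                if group != "control" and min(e, n - e, e_ctrl, n_ctrl - e_ctrl) > 0
                else None
            )
            rows.append({
                "condition": cond,
                "group": group,
                "errors": e,
                "total": n,
                "proportion": e / n if n else float("nan"),
                "se": proportion_se(e, n) if n else float("nan"),
                "log_odds_vs_control": lor.estimate if lor else float("nan"),
                "log_odds_se": lor.se if lor else float("nan"),
                "z_vs_control": lor.z if lor else float("nan"),
            })
    for group in GROUPS:
        e1, n1 = cell(group, "prev_error_uncorrected")
        e2, n2 = cell(group, "prev_error_corrected")
        contrast = log_odds_ratio(
            e1, n1 - e1, e2, n2 - e2,
            comparison=f"{group}: prev Error-c vs Error+c",
        )
        rows.append({
            "condition": "prev_error_uncorrected_vs_corrected",
            "group": group,
            "errors": e1,
            "total": n1,
            "proportion": float("nan"),
            "se": float("nan"),
            "log_odds_vs_control": contrast.estimate,
            "log_odds_se": contrast.se,
            "z_vs_control": contrast.z,
        })
    return pd.DataFrame(rows)


def make_table4(df: pd.DataFrame) -> pd.DataFrame:
    """Run-length table: error proportion per group x run type x length bin,
    with two-tailed log-odds-ratio significance stars (5% *, 1% **) against
    the corresponding length-1 proportion."""
    counts = run_lengths(df)
    idx = counts.set_index(["group", "run_type", "length"])
    rows = []
    for (group, run_type, length), row in idx.iterrows():
        e, n = int(row["errors"]), int(row["total"])
        e1, n1 = (int(v) for v in idx.loc[(group, run_type, "1")])
        stars = ""
        if length != "1" and n > 0 and n1 > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lor = log_odds_ratio(e, n - e, e1, n1 - e1)
            stars = "**" if lor.p < 0.01 else ("*" if lor.p < 0.05 else "")
        rows.append({
            "group": group,
            "run_type": run_type,
            "length": length,
            "errors": e,
            "total": n,
            "proportion": e / n if n else float("nan"),
            "significance": stars,
        })
    return pd.DataFrame(rows)
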