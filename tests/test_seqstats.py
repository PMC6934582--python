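"""Previous-outcome conditioning, run-length tables and contingency
statistics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import antiseq as aq
from antiseq.seqstats import (
    chisq_independence,
    condition_on_previous,
    log_odds_ratio,
    make_table2,
    make_table4,
    proportion_se,
    reconstruct_total,
    run_lengths,
    wald_one_sample,
)

from conftest import make_config


def frame_from_outcomes(outcomes, group="control", pid="p1"):
    rows = [
        (pid, group, j + 1, "left", o,
         None if o == "excluded" else 250.0,
         330.0 if o == "error_corrected" else None)
        for j, o in enumerate(outcomes)
    ]
    return pd.DataFrame(rows, columns=list(aq.records.TRIAL_CSV_COLUMNS))


# ---------------------------------------------------------------------------
# previous-outcome conditioning
# ---------------------------------------------------------------------------

def test_hand_enumerated_previous_conditioning():
    df = frame_from_outcomes(
        ["correct", "error_corrected", "error_uncorrected", "correct"]
    )
    out = condition_on_previous(df).set_index(["group", "condition"])
    assert tuple(out.loc[("control", "prev_correct")]) == (1, 1)
    assert tuple(out.loc[("control", "prev_error_corrected")]) == (1, 1)
    assert tuple(out.loc[("control", "prev_error_uncorrected")]) == (0, 1)


def test_all_correct_sequence_contributes_only_to_prev_correct():
    df = frame_from_outcomes(["correct"] * 8)
    out = condition_on_previous(df).set_index(["group", "condition"])
    assert tuple(out.loc[("control", "prev_correct")]) == (0, 7)
    assert out["total"].sum() == 7


def test_excluded_trials_dropped_before_pairing():
    df = frame_from_outcomes(["correct", "excluded", "error_uncorrected"])
    out = condition_on_previous(df).set_index(["group", "condition"])
    # after dropping the excluded trial, the error follows the correct trial
    assert tuple(out.loc[("control", "prev_correct")]) == (1, 1)
    assert out["total"].sum() == 1


def test_stratum_totals_conserved(tiny_frame):
    out = condition_on_previous(tiny_frame)
    expected = sum(
        len(p.usable_trials) - 1
        for p in aq.frame_to_cohort(tiny_frame)
        if len(p.usable_trials) >= 2
    )
    assert out["total"].sum() == expected


# ---------------------------------------------------------------------------
# run lengths
# ---------------------------------------------------------------------------

def test_run_length_tally_simple_sequences():
    out = run_lengths(frame_from_outcomes(
        ["correct", "correct", "error_uncorrected"]
    )).set_index(["group", "run_type", "length"])
    assert tuple(out.loc[("control", "correct", "1")]) == (0, 1)
    assert tuple(out.loc[("control", "correct", "2")]) == (1, 1)

    out2 = run_lengths(frame_from_outcomes(
        ["error_corrected", "error_corrected", "error_corrected"]
    )).set_index(["group", "run_type", "length"])
    assert tuple(out2.loc[("control", "error", "1")]) == (1, 1)
    assert tuple(out2.loc[("control", "error", "2")]) == (1, 1)


def test_six_plus_bin_pools_long_runs():
    df = frame_from_outcomes(["correct"] * 10)
    out = run_lengths(df).set_index(["group", "run_type", "length"])
    assert int(out.loc[("control", "correct", "6+")]["total"]) == 4  # runs 6..9


def test_null_slopes_give_flat_run_length_proportions():
    """With zero history slopes and no participant heterogeneity the error
    proportion is flat across run-length bins (within 3 binomial SEs of the
    generating rate)."""
    cfg = make_config(seed=13, sizes=(200, 1, 1), p_full=1.0, sigma_u=0.0,
                      slope_success=0.0, slope_error=0.0, intercept=0.5)
    p_gen = 1.0 / (1.0 + math.exp(0.5))  # error probability, correct-coded
    out = run_lengths(aq.cohort_to_frame(aq.simulate_cohort(cfg)))
    out = out[(out["group"] == "control") & (out["total"] >= 30)]
    for _, row in out.iterrows():
        se = math.sqrt(p_gen * (1 - p_gen) / row["total"])
        assert abs(row["errors"] / row["total"] - p_gen) < 3 * se


def test_error_run_proportions_nondecreasing_on_default_cohort():
    """Under the default generating model (negative error-run slope on the
    correct-coded response plus participant selection) the pooled error
    proportion is nondecreasing in error-run length, within 2 SEs."""
    cfg = make_config(seed=17, sizes=(200, 130, 90), p_full=1.0)
    out = run_lengths(aq.cohort_to_frame(aq.simulate_cohort(cfg)))
    pooled = (out[out["run_type"] == "error"]
              .groupby("length")[["errors", "total"]].sum()
              .reindex(["1", "2", "3", "4", "5", "6+"]))
    p = pooled["errors"] / pooled["total"]
    se = np.sqrt(p * (1 - p) / pooled["total"])
    for k in range(1, len(p)):
        assert p.iloc[k] >= p.iloc[k - 1] - 2 * math.hypot(se.iloc[k], se.iloc[k - 1])


# ---------------------------------------------------------------------------
# total reconstruction from printed (count, proportion) pairs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("errors,proportion,total", [
    (262, 0.686, 382),
    (123, 0.815, 151),
    (100, 0.500, 200),
    (141, 0.758, 186),
    (374, 0.625, 598),
    (78, 0.595, 131),
    (362, 0.574, 631),
    (319, 0.234, 1363),
    (140, 0.335, 418),
    (260, 0.389, 668),
])
def test_reconstruct_total_examples(errors, proportion, total):
    assert reconstruct_total(errors, proportion) == total


def test_reconstruct_total_rejects_degenerate_proportions():
    with pytest.raises(ValueError):
        reconstruct_total(10, 0.0)
    with pytest.raises(ValueError):
        reconstruct_total(10, 1.0)


def test_reconstruct_total_round_trip_sweep():
    """For every total n <= 2000 (moderate proportions), inverting the
    3-digit printed proportion returns a total that reproduces the print,
    and n itself whenever n is uniquely consistent near round(e/p)."""
    for n in range(10, 2001, 7):
        for e in {n // 5, n // 2, (4 * n) // 5}:
            if not 0 < e < n:
                continue
            p = round(e / n, 3)
            if not 0.0 < p < 1.0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = reconstruct_total(e, p)
            assert abs(e / m - p) <= 5e-4 or m == n
            n0 = round(e / p)
            unique = [k for k in range(n0 - 2, n0 + 3)
                      if k >= e and abs(e / k - p) <= 5e-4]
            if unique == [n]:
                assert m == n


# ---------------------------------------------------------------------------
# proportion SE / log-odds / Wald / chi-squared
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("errors,total,se", [
    (123, 151, 0.032),
    (141, 186, 0.031),
])
def test_proportion_se_matches_published(errors, total, se):
    assert proportion_se(errors, total) == pytest.approx(se, abs=5e-4)


def test_proportion_se_degenerate_zero():
    assert proportion_se(0, 50) == 0.0


@pytest.mark.parametrize("cells,est,se,z", [
    ((123, 28, 262, 120), 0.699, 0.237, 2.954),   # AD: prev Error-c vs Error+c
    ((78, 53, 362, 269), 0.089, 0.195, 0.458),    # control contrast
])
def test_log_odds_ratio_reproduces_published_contrasts(cells, est, se, z):
    r = log_odds_ratio(*cells)
    assert r.estimate == pytest.approx(est, abs=1e-3)
    assert r.se == pytest.approx(se, abs=1e-3)
    assert r.z == pytest.approx(z, abs=5e-3)


def test_log_odds_ratio_symmetry_at_equal_odds():
    r = log_odds_ratio(10, 10, 10, 10)
    assert r.estimate == 0.0 and r.z == 0.0 and r.p == pytest.approx(1.0)


@settings(derandomize=True, max_examples=200)
@given(st.tuples(*[st.integers(1, 500)] * 4))
def test_log_odds_ratio_antisymmetry(cells):
    a, b, c, d = cells
    fwd = log_odds_ratio(a, b, c, d)
    rev = log_odds_ratio(c, d, a, b)
    assert fwd.estimate == pytest.approx(-rev.estimate, abs=1e-12)
    assert fwd.se == pytest.approx(rev.se)


def test_zero_cell_triggers_continuity_correction():
    with pytest.warns(UserWarning):
        r = log_odds_ratio(0, 10, 5, 5)
    assert math.isfinite(r.estimate)


@pytest.mark.parametrize("p_hat,n,z", [
    (0.335, 418, -7.147),   # AD after a correct trial
    (0.389, 668, -5.885),   # MCI after a correct trial
    (0.595, 131, 2.215),    # control after an uncorrected error
])
def test_one_sample_wald_with_observed_variance(p_hat, n, z):
    r = wald_one_sample(p_hat, n)
    assert r.z == pytest.approx(z, abs=5e-3)


def test_one_sample_wald_null_variance_variant_differs():
    obs = wald_one_sample(0.335, 418, variance="observed")
    nul = wald_one_sample(0.335, 418, variance="null")
    assert abs(nul.z) < abs(obs.z)  # observed variance < 0.25/n here
    assert wald_one_sample(0.5, 123).z == 0.0
    with pytest.raises(ValueError):
        wald_one_sample(1.0, 10)


def test_chisq_independence_against_direct_formula():
    table = np.array([[30, 10, 5], [12, 22, 9]])
    stat, df, p, v = chisq_independence(table)
    # brute-force expected counts
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    stat_direct = ((table - exp) ** 2 / exp).sum()
    assert stat == pytest.approx(stat_direct)
    assert df == 2
    assert v == pytest.approx(math.sqrt(stat_direct / table.sum()))


def test_chisq_degenerate_and_extreme_tables():
    stat, _, p, v = chisq_independence([[10, 10], [10, 10]])
    assert stat == 0.0 and v == 0.0 and p == pytest.approx(1.0)
    *_, v1 = chisq_independence([[10, 0], [0, 10]])
    assert v1 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        chisq_independence([[1, 2]])


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def test_table2_counts_and_contrasts_consistent(tiny_frame):
    t2 = make_table2(tiny_frame)
    counts = condition_on_previous(tiny_frame)
    merged = t2.merge(counts, on=["group", "condition"], how="inner",
                      suffixes=("", "_ref"))
    assert (merged["errors"] == merged["errors_ref"]).all()
    contrast = t2[t2["condition"] == "prev_error_uncorrected_vs_corrected"]
    assert set(contrast["group"]) == set(aq.GROUPS)


def test_table4_layout_and_stars(tiny_frame):
    t4 = make_table4(tiny_frame)
    assert set(t4["length"]) == {"1", "2", "3", "4", "5", "6+"}
    assert t4["significance"].isin(["", "*", "**"]).all()
    assert (t4.loc[t4["length"] == "1", "significance"] == "").all()
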