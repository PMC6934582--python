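"""Random-intercept logistic model: quadrature accuracy, boundary behaviour,
nested tests, bootstrap and average-participant prediction."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special, stats

import antiseq as aq
from antiseq.glmm import (
    GlmmSpec,
    bootstrap_sigma_ci,
    build_design,
    deviance_test,
    fit_glmm,
    marginal_loglik,
    predict_average,
)

from conftest import make_config


def toy_frame(seed=0, n_part=5, n_trials=4, sigma=1.0, beta0=0.3, beta1=0.5):
    """Tiny fixed dataset with one numeric covariate."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_part):
        u = rng.normal(0, sigma)
        for j in range(1, n_trials + 1):
            x = rng.normal()
            y = rng.random() < special.expit(beta0 + beta1 * x + u)
            rows.append((f"p{i}", "control", j, "left",
                         "error_corrected" if y else "correct",
                         200.0, 330.0 if y else None, x))
    return pd.DataFrame(rows, columns=[*aq.records.TRIAL_CSV_COLUMNS, "x"])


def grid_loglik(design, beta, sigma, n_grid=2001, span=10.0):
    """Brute-force marginal log-likelihood on a trapezoid grid."""
    grid = np.linspace(-span, span, n_grid)
    eta = design.X @ np.asarray(beta)
    total = 0.0
    for g in range(design.group_idx.max() + 1):
        m = design.group_idx == g
        et = eta[m][None, :] + grid[:, None]
        y = design.y[m]
        ll = (y * special.log_expit(et) + (1 - y) * special.log_expit(-et)).sum(axis=1)
        dens = np.exp(ll) * stats.norm.pdf(grid, scale=sigma)
        total += math.log(np.trapezoid(dens, grid))
    return total


# ---------------------------------------------------------------------------
# likelihood correctness
# ---------------------------------------------------------------------------

def test_quadrature_matches_grid_integration_on_toy():
    design = build_design(toy_frame(), GlmmSpec(fixed=("x",),
                                                response_coding="error"))
    for beta, sigma in [((0.3, 0.5), 1.0), ((-0.2, 1.1), 0.4), ((0.0, 0.0), 2.0)]:
        agq = marginal_loglik(design, np.array(beta), sigma, n_quad=15)
        grid = grid_loglik(design, beta, sigma)
        assert agq == pytest.approx(grid, abs=1e-6)


def test_quadrature_order_convergence(tiny_frame):
    design = build_design(aq.add_history_covariates(tiny_frame), GlmmSpec())
    beta = np.array([0.7, -0.2, -0.3, 0.05, -0.04])
    ll15 = marginal_loglik(design, beta, 1.4, n_quad=15)
    ll41 = marginal_loglik(design, beta, 1.4, n_quad=41)
    assert abs(ll15 - ll41) < 1e-6


def test_response_coding_flip_negates_coefficients(medium_cov):
    d_cor = build_design(medium_cov, GlmmSpec(response_coding="correct"))
    d_err = build_design(medium_cov, GlmmSpec(response_coding="error"))
    beta = np.array([0.7, -0.2, -0.3, 0.05, -0.04])
    ll_c = marginal_loglik(d_cor, beta, 1.2)
    ll_e = marginal_loglik(d_err, -beta, 1.2)
    assert ll_c == pytest.approx(ll_e, abs=1e-8)


def test_sigma_zero_data_reduces_to_logistic_oracle():
    """On data generated without participant heterogeneity the GLMM collapses
    to plain logistic regression: coefficients match the statsmodels Logit
    oracle to 1e-6 and sigma_u is estimated at (or flagged near) zero."""
    cfg = make_config(seed=8, sizes=(30, 20, 15), sigma_u=0.0)
    cov = aq.add_history_covariates(aq.cohort_to_frame(aq.simulate_cohort(cfg)))
    fit = fit_glmm(cov)
    assert fit.sigma_u <= 0.05
    design = build_design(cov, GlmmSpec())
    oracle = sm.Logit(design.y, design.X).fit(disp=0, tol=1e-12)
    if fit.boundary:
        assert np.allclose(fit.beta.to_numpy(), oracle.params, atol=1e-6)
    else:
        # sigma landed near but not at the boundary; estimates still agree
        assert np.allclose(fit.beta.to_numpy(), oracle.params, atol=5e-3)


def test_rank_deficient_design_rejected(medium_cov):
    cov = medium_cov.copy()
    cov["dup"] = cov["n_prev_success"]
    with pytest.raises(ValueError):
        fit_glmm(cov, GlmmSpec(fixed=("group", "n_prev_success", "dup")))


def test_too_few_participants_rejected():
    df = toy_frame(n_part=1)
    with pytest.raises(ValueError):
        fit_glmm(df, GlmmSpec(fixed=("x",)))


# ---------------------------------------------------------------------------
# deviance tests
# ---------------------------------------------------------------------------

def test_identical_models_give_zero_deviance(medium_fit):
    stat, df, p = deviance_test(medium_fit, medium_fit)
    assert stat == 0.0 and df == 0 and p == 1.0


def test_non_nested_models_rejected(medium_cov, medium_fit):
    other = fit_glmm(medium_cov, GlmmSpec(fixed=("n_prev_success",)))
    with pytest.raises(ValueError):
        deviance_test(other, medium_fit)


def test_random_effect_overwhelmingly_significant(medium_cov, medium_fit):
    """On a sigma_u ~ 1.4 cohort the random intercept is decisively needed:
    the deviance statistic dwarfs the 1-df critical value."""
    reduced = fit_glmm(medium_cov, GlmmSpec(random_intercept=False))
    stat, df, p = deviance_test(medium_fit, reduced)
    assert df == 1
    assert stat > 50.0
    assert p < 1e-10


def test_null_deviance_is_chi_squared_calibrated():
    """Adding a truly null covariate: the deviance statistic over replicate
    null cohorts follows chi-squared(1)."""
    rng = np.random.default_rng(0)
    stats_out = []
    for rep in range(100):
        cfg = make_config(seed=1000 + rep, sizes=(14, 1, 1), n_trials=10,
                          p_full=1.0, sigma_u=0.8)
        cov = aq.add_history_covariates(
            aq.cohort_to_frame(aq.simulate_cohort(cfg)))
        cov["noise"] = rng.normal(size=len(cov))
        full = fit_glmm(cov, GlmmSpec(fixed=("noise",)))
        reduced = fit_glmm(cov, GlmmSpec(fixed=()))
        stats_out.append(deviance_test(full, reduced)[0])
    ks = stats.kstest(stats_out, stats.chi2(1).cdf)
    assert ks.pvalue > 0.005


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_input_validation_and_determinism(medium_fit):
    with pytest.raises(ValueError):
        bootstrap_sigma_ci(medium_fit, B=0)
    a = bootstrap_sigma_ci(medium_fit, B=8, seed=3)
    b = bootstrap_sigma_ci(medium_fit, B=8, seed=3)
    assert a.interval == b.interval
    assert a.interval[0] < medium_fit.sigma_u < a.interval[1]


def test_bootstrap_interval_covers_generating_sigma():
    """Reduced-scale coverage check: the generating sigma_u falls inside the
    bootstrap 95% CI in >=90% of outer replicates."""
    sigma_true = 1.374
    cover = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = make_config(seed=500 + rep, sizes=(15, 10, 8), n_trials=16,
                          p_full=1.0)
        cov = aq.add_history_covariates(
            aq.cohort_to_frame(aq.simulate_cohort(cfg)))
        fit = fit_glmm(cov, GlmmSpec(fixed=("group",)))
        lo, hi = bootstrap_sigma_ci(fit, B=30, seed=rep).interval
        cover += lo <= sigma_true <= hi
    assert cover / n_rep >= 0.9


# ---------------------------------------------------------------------------
# average-participant prediction
# ---------------------------------------------------------------------------

def test_zero_linear_predictor_gives_half(medium_fit):
    zeroed = dataclasses.replace(medium_fit, beta=medium_fit.beta * 0.0)
    p, (lo, hi) = predict_average(
        zeroed, {"group": "control", "n_prev_success": 0, "n_prev_fail": 0}
    )
    assert p == 0.5 and lo < 0.5 < hi


def test_predicted_error_probability_increases_with_error_run(medium_fit):
    """Correct-coded fit with a negative error-run slope: the average
    participant's error probability rises with preceding error-run length."""
    assert medium_fit.beta["n_prev_fail"] < 0
    probs = [
        1.0 - predict_average(medium_fit, {"group": "AD", "n_prev_success": 0,
                                           "n_prev_fail": k})[0]
        for k in range(6)
    ]
    assert all(b > a for a, b in zip(probs, probs[1:]))


def test_prediction_ci_matches_monte_carlo_oracle(medium_fit):
    x = {"group": "MCI", "n_prev_success": 2, "n_prev_fail": 0}
    p, (lo, hi) = predict_average(medium_fit, x)
    beta = medium_fit.beta.to_numpy()
    vb = medium_fit.vcov.to_numpy()[:len(beta), :len(beta)]
    from antiseq.glmm import _encode_row
    xv = _encode_row(medium_fit, x)
    rng = np.random.default_rng(4)
    draws = special.expit(rng.multivariate_normal(beta, vb, size=10_000) @ xv)
    mc_lo, mc_hi = np.quantile(draws, [0.025, 0.975])
    assert lo == pytest.approx(mc_lo, abs=0.005)
    assert hi == pytest.approx(mc_hi, abs=0.005)


def test_covariates_outside_design_rejected(medium_fit):
    with pytest.raises(ValueError):
        predict_average(medium_fit, {"group": "AD", "n_prev_success": 0,
                                     "n_prev_fail": 0, "age": 70})
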