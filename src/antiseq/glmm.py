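"""Logistic generalized linear mixed model with a participant random
intercept, fitted by maximum likelihood with adaptive Gauss-Hermite
quadrature.

Model
-----
For participant i, trial j, the binary response y_ij (by default coded 1 for
a *correct* antisaccade; flippable) follows

    y_ij | u_i ~ Bernoulli(p_ij),   logit(p_ij) = x_ij' beta + u_i,
    u_i ~ Normal(0, sigma_u^2),

with fixed effects typically: treatment-coded cognitive group (control
reference) plus the run-length covariates ``n_prev_success`` and
``n_prev_fail`` (mutually exclusive counts of immediately preceding
consecutive correct / error trials), or the previous-trial outcome category.

The marginal likelihood integrates the random intercept out per participant;
because the random effect is a scalar, adaptive Gauss-Hermite quadrature
(integrand re-centred at its mode, default 15 nodes) is effectively exact.
Standard errors come from the inverse observed information (finite-difference
Hessian at the optimum, parameterised in (beta, log sigma_u)). When the
variance component collapses to the boundary the model reduces to ordinary
logistic regression; the fit is then completed by an in-module Newton solver
and flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss  # noqa: F401  (see _gh_nodes)
from scipy import optimize, special, stats

from .records import ERROR_OUTCOMES, GROUPS, OUTCOME_EXCLUDED

log = logging.getLogger(__name__)

_LOG_SIGMA_MIN = -10.0  # effective sigma floor ~4.5e-5: boundary territory
_BOUNDARY_SIGMA = 1e-2


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification.

    ``fixed`` names columns of the trial-level table; ``group`` expands to
    treatment-coded indicators with control as reference, ``prev_outcome``
    to indicators with the previous-correct category as reference, any other
    column enters numerically. ``response_coding='correct'`` models the
    probability of a correct antisaccade (the sign convention under which
    run-length slopes are reported here); ``'error'`` flips the response and
    negates every coefficient.
    """

    fixed: tuple = ("group", "n_prev_success", "n_prev_fail")
    response_coding: str = "correct"
    random_intercept: bool = True
    participant_col: str = "participant_id"

    def validate(self) -> None:
        if self.response_coding not in ("correct", "error"):
            raise ValueError("response_coding must be 'correct' or 'error'")
        # an empty ``fixed`` is allowed: intercept-only model


@dataclass
class GlmmFit:
    """A fitted model: coefficients (log-odds), SEs, random-intercept SD,
    log-likelihood and covariance of (beta, log sigma_u)."""

    beta: pd.Series
    se_beta: pd.Series
    sigma_u: float
    sigma_u_se: float
    loglik: float
    vcov: pd.DataFrame
    converged: bool
    boundary: bool
    n_quad: int
    n_obs: int
    n_participants: int
    spec: GlmmSpec
    message: str = ""
    # design internals retained for nested tests / bootstrap / prediction
    design: "Design" = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.beta) + (1 if self.spec.random_intercept else 0)


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    names: list
    group_idx: np.ndarray
    group_ids: list
    group_labels: np.ndarray  # cognitive-group label per participant


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, spec: GlmmSpec) -> Design:
    """Encode a trial-level table into (y, X) with the spec's coding.

    Excluded trials and rows with missing covariates are dropped; rows are
    ordered so each participant's trials are contiguous (required by the
    per-participant likelihood).
    """
    spec.validate()
    d = df[df["outcome"] != OUTCOME_EXCLUDED].copy()
    d = d.sort_values([spec.participant_col, "trial_index"], kind="stable")

    cols = [c for c in spec.fixed if c not in ("group",)]
    needed = [c for c in cols if c in d.columns]
    missing = [c for c in cols if c not in d.columns]
    if missing:
        raise ValueError(f"covariate columns not in data: {missing}")
    d = d.dropna(subset=[c for c in needed if c != "prev_outcome"] +
                        (["prev_outcome"] if "prev_outcome" in cols else []))

    is_error = d["outcome"].isin(ERROR_OUTCOMES).to_numpy()
    y = (~is_error if spec.response_coding == "correct" else is_error)
    y = y.astype(float)

    parts: list[np.ndarray] = [np.ones(len(d))]
    names: list[str] = ["intercept"]
    for col in spec.fixed:
        if col == "group":
            # control is the reference level; absent levels are not encoded
            present = [g for g in GROUPS if (d["group"] == g).any()]
            for g in present[1:]:
                parts.append((d["group"] == g).to_numpy(float))
                names.append(f"group[{g}]")
        elif col == "prev_outcome":
            for level in ("prev_error_corrected", "prev_error_uncorrected"):
                parts.append((d["prev_outcome"] == level).to_numpy(float))
                names.append(f"prev_outcome[{level}]")
        else:
            parts.append(d[col].to_numpy(float))
            names.append(col)
    X = np.column_stack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")

    codes, uniques = pd.factorize(d[spec.participant_col], sort=False)
    glabels = d.groupby(spec.participant_col, sort=False)["group"].first()
    return Design(
        y=y, X=X, names=names, group_idx=codes.astype(np.int64),
        group_ids=list(uniques), group_labels=glabels.to_numpy(),
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _gh_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Physicists' Gauss-Hermite nodes/weights (weight e^{-z^2})."""
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    return z, np.log(w)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * special.log_expit(eta) + (1.0 - y) * special.log_expit(-eta)


class _MarginalLikelihood:
    """Adaptive Gauss-Hermite marginal log-likelihood for one design."""

    def __init__(self, design: Design, n_quad: int = 15):
        self.d = design
        self.n_quad = n_quad
        self.z, self.logw = _gh_nodes(n_quad)
        self.G = int(design.group_idx.max()) + 1 if len(design.y) else 0
        # reduceat boundaries: trials are contiguous per participant
        change = np.flatnonzero(np.diff(design.group_idx)) + 1
        self.starts = np.concatenate(([0], change))
        self._u_cache = np.zeros(self.G)

    def _find_modes(self, eta: np.ndarray, sigma: float
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised Newton for the per-participant posterior modes."""
        gi = self.d.group_idx
        y = self.d.y
        u = self._u_cache.copy()
        inv_s2 = 1.0 / (sigma * sigma)
        for _ in range(100):
            p = special.expit(eta + u[gi])
            grad = np.bincount(gi, weights=y - p, minlength=self.G) - u * inv_s2
            hess = -(np.bincount(gi, weights=p * (1 - p), minlength=self.G)
                     + inv_s2)
            delta = np.clip(grad / -hess, -4.0, 4.0)
            u += delta
            if np.max(np.abs(delta)) < 1e-11:
                break
        p = special.expit(eta + u[gi])
        hess = -(np.bincount(gi, weights=p * (1 - p), minlength=self.G) + inv_s2)
        self._u_cache = u
        return u, 1.0 / np.sqrt(-hess)

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        eta = self.d.X @ beta
        if sigma < 1e-8:
            return float(_bernoulli_loglik(eta, self.d.y).sum())
        u_hat, tau = self._find_modes(eta, sigma)
        U = u_hat[None, :] + math.sqrt(2.0) * tau[None, :] * self.z[:, None]
        ET = eta[None, :] + U[:, self.d.group_idx]
        ll_obs = _bernoulli_loglik(ET, self.d.y[None, :])
        ll_grp = np.add.reduceat(ll_obs, self.starts, axis=1)
        log_prior = (-0.5 * math.log(2.0 * math.pi) - math.log(sigma)
                     - 0.5 * (U / sigma) ** 2)
        h = ll_grp + log_prior
        inner = special.logsumexp(
            self.logw[:, None] + self.z[:, None] ** 2 + h, axis=0
        )
        return float(np.sum(0.5 * math.log(2.0) + np.log(tau) + inner))


def marginal_loglik(design: Design, beta: np.ndarray, sigma: float,
                    n_quad: int = 15) -> float:
    """Marginal log-likelihood at given parameters (exposed so independent
    integration oracles can be compared against the same quantity)."""
    return _MarginalLikelihood(design, n_quad).loglik(np.asarray(beta, float),
                                                      float(sigma))


# ---------------------------------------------------------------------------
# plain logistic Newton solver (sigma = 0 limit; also supplies start values)
# ---------------------------------------------------------------------------

def _logistic_newton(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                     max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton-Raphson logistic regression; returns (beta, vcov, loglik)."""
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        step = np.linalg.solve(H + 1e-12 * np.eye(p_dim), grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = special.expit(eta)
    H = X.T @ (X * (mu * (1 - mu))[:, None])
    vcov = np.linalg.inv(H)
    return beta, vcov, float(_bernoulli_loglik(eta, y).sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_glmm(df: pd.DataFrame, spec: GlmmSpec | None = None, n_quad: int = 15,
             start: np.ndarray | None = None) -> GlmmFit:
    """Fit the random-intercept logistic model by adaptive-quadrature ML.

    Requires at least two participants with two or more trials each. The
    optimiser starts from the plain logistic solution with sigma_u = 1 and
    converges deterministically for given data and start values.
    Non-convergence is flagged on the returned fit, never silent; a variance
    component at the boundary (sigma ~ 0) is flagged and the coefficients
    are completed by the exact logistic Newton solve.
    """
    spec = spec or GlmmSpec()
    design = build_design(df, spec)
    counts = np.bincount(design.group_idx)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 participants with >= 2 trials each")

    beta0, vcov0, ll0 = _logistic_newton(design.X, design.y)

    if not spec.random_intercept:
        names = design.names
        return GlmmFit(
            beta=pd.Series(beta0, index=names),
            se_beta=pd.Series(np.sqrt(np.diag(vcov0)), index=names),
            sigma_u=0.0, sigma_u_se=float("nan"), loglik=ll0,
            vcov=pd.DataFrame(vcov0, index=names, columns=names),
            converged=True, boundary=False, n_quad=0,
            n_obs=len(design.y), n_participants=len(design.group_ids),
            spec=spec, message="logistic regression (no random intercept)",
            design=design,
        )

    ml = _MarginalLikelihood(design, n_quad)
    n = len(design.y)
    p_dim = design.X.shape[1]

    def negloglik(theta: np.ndarray) -> float:
        return -ml.loglik(theta[:p_dim], math.exp(theta[p_dim])) / n

    theta0 = (np.concatenate([beta0, [0.0]]) if start is None
              else np.asarray(start, float))
    bounds = [(None, None)] * p_dim + [(_LOG_SIGMA_MIN, 5.0)]
    res = optimize.minimize(
        negloglik, theta0, method="L-BFGS-B", jac="3-point", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    theta = res.x
    sigma = math.exp(theta[p_dim])
    loglik = -res.fun * n
    converged = bool(res.success)
    boundary = sigma < _BOUNDARY_SIGMA
    message = str(res.message)
    names = design.names

    if boundary:
        log.warning("sigma_u at boundary (%.3g); reducing to plain logistic", sigma)
        beta_hat, vcov_b, loglik = _logistic_newton(design.X, design.y)
        se = np.sqrt(np.diag(vcov_b))
        vcov_full = np.full((p_dim + 1, p_dim + 1), np.nan)
        vcov_full[:p_dim, :p_dim] = vcov_b
        idx = names + ["log_sigma_u"]
        return GlmmFit(
            beta=pd.Series(beta_hat, index=names),
            se_beta=pd.Series(se, index=names),
            sigma_u=0.0, sigma_u_se=float("nan"), loglik=loglik,
            vcov=pd.DataFrame(vcov_full, index=idx, columns=idx),
            converged=converged, boundary=True, n_quad=n_quad,
            n_obs=n, n_participants=len(design.group_ids), spec=spec,
            message=message + "; sigma_u at boundary", design=design,
        )

    H = _central_hessian(lambda th: -ml.loglik(th[:p_dim], math.exp(th[p_dim])),
                         theta)
    try:
        vcov = np.linalg.inv(H)
        if np.any(np.diag(vcov)[:p_dim] <= 0):
            raise np.linalg.LinAlgError("non-PD information")
        se = np.sqrt(np.diag(vcov)[:p_dim])
        se_s = math.sqrt(max(vcov[p_dim, p_dim], 0.0))
    except np.linalg.LinAlgError:
        converged = False
        message += "; observed information not positive definite"
        vcov = np.full((p_dim + 1, p_dim + 1), np.nan)
        se = np.full(p_dim, np.nan)
        se_s = float("nan")

    idx = names + ["log_sigma_u"]
    return GlmmFit(
        beta=pd.Series(theta[:p_dim], index=names),
        se_beta=pd.Series(se, index=names),
        sigma_u=sigma, sigma_u_se=sigma * se_s,  # delta method from log scale
        loglik=loglik,
        vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        converged=converged, boundary=False, n_quad=n_quad,
        n_obs=n, n_participants=len(design.group_ids), spec=spec,
        message=message, design=design,
    )


def _central_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# nested-model deviance test
# ---------------------------------------------------------------------------

def deviance_test(fit_full: GlmmFit, fit_reduced: GlmmFit
                  ) -> tuple[float, int, float]:
    """Likelihood-ratio (deviance) test of nested fits on the same data.

    Returns (statistic, df, p) with statistic = 2 (ll_full - ll_reduced)
    against chi-squared(df), df = difference in parameter count. A test of
    the variance component sits on the boundary of its parameter space, so
    the chi-squared reference is conservative there (logged).
    """
    if not set(fit_reduced.beta.index) <= set(fit_full.beta.index):
        raise ValueError("reduced model fixed effects not nested in full model")
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("fits use different data")
    df_diff = fit_full.n_params - fit_reduced.n_params
    if df_diff < 0:
        raise ValueError("reduced model has more parameters than full model")
    if fit_reduced.spec.random_intercept != fit_full.spec.random_intercept:
        log.warning("variance-component test: chi-squared reference is "
                    "conservative at the boundary")
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = 1.0 if df_diff == 0 else float(stats.chi2.sf(stat, df_diff))
    return stat, df_diff, p


# ---------------------------------------------------------------------------
# parametric bootstrap for sigma_u
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    interval: tuple
    sigmas: np.ndarray
    n_failed: int


def simulate_response(fit: GlmmFit, rng: np.random.Generator) -> np.ndarray:
    """Draw a response vector from the fitted model (design held fixed)."""
    d = fit.design
    u = rng.normal(0.0, fit.sigma_u, size=len(d.group_ids))
    p = special.expit(d.X @ fit.beta.to_numpy() + u[d.group_idx])
    return (rng.random(len(p)) < p).astype(float)


def _run_length_columns(names: list) -> tuple[int, int] | None:
    try:
        return names.index("n_prev_success"), names.index("n_prev_fail")
    except ValueError:
        return None


def simulate_sequences(fit: GlmmFit, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Regenerate whole trial sequences from a run-length fit.

    The run-length covariates are outcome-derived, so a faithful parametric
    bootstrap must recompute them from the simulated history rather than
    holding the design fixed: each participant's trials are simulated
    sequentially, the run counters updated from the simulated outcomes.
    Returns the new response vector and the updated design matrix. Requires
    the remaining fixed effects to be constant within participant.
    """
    d = fit.design
    idx = _run_length_columns(d.names)
    if idx is None:
        raise ValueError("fit has no run-length covariates to regenerate")
    i_s, i_f = idx
    beta = fit.beta.to_numpy()
    b_s, b_f = beta[i_s], beta[i_f]
    base_eta = d.X @ beta - b_s * d.X[:, i_s] - b_f * d.X[:, i_f]
    u = rng.normal(0.0, fit.sigma_u, size=len(d.group_ids))
    unif = rng.random(len(d.y))
    y = np.empty(len(d.y))
    X = d.X.copy()
    gi = d.group_idx
    rs = rf = 0
    for j in range(len(y)):
        if j == 0 or gi[j] != gi[j - 1]:
            rs = rf = 0
        X[j, i_s], X[j, i_f] = rs, rf
        eta = base_eta[j] + u[gi[j]] + b_s * rs + b_f * rf
        hit = unif[j] < special.expit(eta)
        y[j] = 1.0 if hit else 0.0
        if hit:
            rs, rf = rs + 1, 0
        else:
            rs, rf = 0, rf + 1
    return y, X


def bootstrap_sigma_ci(fit: GlmmFit, B: int = 500, seed: int = 0,
                       level: float = 0.95,
                       regenerate: str = "auto") -> BootstrapResult:
    """Parametric-bootstrap percentile CI for the random-intercept SD.

    Simulates B datasets from the fitted model, refits each, and takes the
    2.5/97.5 percentiles of the sigma_u estimates. When the fit contains
    run-length covariates (``regenerate='auto'`` or ``'sequences'``) whole
    trial sequences are regenerated so the outcome-derived covariates keep
    their sampling distribution; ``regenerate='fixed'`` holds the design
    fixed (the conditional convention of lme4::bootMer). Failed refits are
    dropped (counted); more than 10% failures raises.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if not fit.converged:
        raise ValueError("base fit did not converge")
    if regenerate not in ("auto", "sequences", "fixed"):
        raise ValueError("regenerate must be 'auto', 'sequences' or 'fixed'")
    rng = np.random.default_rng(seed)
    d = fit.design
    dynamic = (regenerate == "sequences"
               or (regenerate == "auto"
                   and _run_length_columns(d.names) is not None))
    theta_hat = np.concatenate([fit.beta.to_numpy(),
                                [math.log(max(fit.sigma_u, 1e-3))]])
    sigmas = []
    n_failed = 0
    for _ in range(B):
        if dynamic:
            y_star, X_star = simulate_sequences(fit, rng)
            design_b = replace(d, y=y_star, X=X_star)
        else:
            design_b = replace(d, y=simulate_response(fit, rng))
        try:
            fit_b = _refit(design_b, fit.spec, fit.n_quad, theta_hat)
        except Exception:  # noqa: BLE001 - failures are counted, not fatal
            n_failed += 1
            continue
        if not fit_b[1]:
            n_failed += 1
            continue
        sigmas.append(fit_b[0])
    if n_failed > 0.1 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap refits failed")
    sigmas = np.asarray(sigmas)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(sigmas, [alpha, 1.0 - alpha])
    return BootstrapResult(interval=(float(lo), float(hi)), sigmas=sigmas,
                           n_failed=n_failed)


def _refit(design: Design, spec: GlmmSpec, n_quad: int,
           start: np.ndarray) -> tuple[float, bool]:
    """Light-weight refit for the bootstrap: returns (sigma_hat, converged)."""
    ml = _MarginalLikelihood(design, n_quad)
    n = len(design.y)
    p_dim = design.X.shape[1]

    def negloglik(theta):
        return -ml.loglik(theta[:p_dim], math.exp(theta[p_dim])) / n

    bounds = [(None, None)] * p_dim + [(_LOG_SIGMA_MIN, 5.0)]
    res = optimize.minimize(
        negloglik, start, method="L-BFGS-B", jac="3-point", bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
    )
    return math.exp(res.x[p_dim]), bool(res.success)


# ---------------------------------------------------------------------------
# average-participant prediction
# ---------------------------------------------------------------------------

def predict_average(fit: GlmmFit, covariates: dict, level: float = 0.95
                    ) -> tuple[float, tuple]:
    """Predicted response probability for an average participant (u = 0).

    ``covariates`` maps design-column values, e.g.
    ``{"group": "AD", "n_prev_fail": 3, "n_prev_success": 0}``. The CI is the
    delta-method interval on the linear predictor mapped through the inverse
    logit (monotone, so it is also the CI of the probability).
    """
    x = _encode_row(fit, covariates)
    beta = fit.beta.to_numpy()
    eta = float(x @ beta)
    vb = fit.vcov.to_numpy()[: len(beta), : len(beta)]
    if np.any(~np.isfinite(vb)):
        raise ValueError("fit has no valid covariance; cannot form CI")
    se = math.sqrt(float(x @ vb @ x))
    zc = stats.norm.ppf(0.5 + level / 2.0)
    p = special.expit(eta)
    return float(p), (float(special.expit(eta - zc * se)),
                      float(special.expit(eta + zc * se)))


def _encode_row(fit: GlmmFit, covariates: dict) -> np.ndarray:
    vals = dict(covariates)
    x = np.zeros(len(fit.beta))
    for k, name in enumerate(fit.beta.index):
        if name == "intercept":
            x[k] = 1.0
        elif name.startswith("group["):
            g = name[len("group["):-1]
            if vals.get("group") not in (None, *GROUPS):
                raise ValueError(f"unknown group {vals.get('group')!r}")
            x[k] = 1.0 if vals.get("group") == g else 0.0
        elif name.startswith("prev_outcome["):
            level = name[len("prev_outcome["):-1]
            x[k] = 1.0 if vals.get("prev_outcome") == level else 0.0
        else:
            if name not in vals:
                raise ValueError(f"missing covariate {name!r}")
            x[k] = float(vals[name])
    extra = set(vals) - {"group", "prev_outcome"} - set(fit.beta.index)
    if extra:
        raise ValueError(f"covariates outside the design: {sorted(extra)}")
    return x


def fit_summary_frame(fit: GlmmFit) -> pd.DataFrame:
    """Coefficient table (estimate, SE, Z, p) in published layout."""
    z = fit.beta / fit.se_beta
    return pd.DataFrame({
        "variable": fit.beta.index,
        "estimate_log_odds": fit.beta.to_numpy(),
        "std_error": fit.se_beta.to_numpy(),
        "z_value": z.to_numpy(),
        "p_value": 2.0 * stats.norm.sf(np.abs(z.to_numpy())),
    })
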