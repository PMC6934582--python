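"""Synthetic antisaccade cohort generator.

The generator produces cohorts with the statistical structure the downstream
analysis assumes, so that every stage — sequential conditioning statistics,
the logistic random-intercept model, and the reaction-time analysis — can be
exercised and validated by parameter recovery without access to raw study
data.

Generative model
----------------
For participant ``i`` in group ``g`` a random intercept ``u_i ~ N(0, σ_u²)``
is drawn. On trial ``j`` the linear predictor

    η_ij = β_0 + δ_g + u_i + β_s · n_prev_success_ij + β_e · n_prev_fail_ij

is the logit of the probability of the *reference outcome* (``correct`` by
default; flippable), where ``n_prev_success`` / ``n_prev_fail`` are the run
lengths of immediately preceding consecutive correct / error trials (exactly
one is nonzero; both are zero on trial 1). Errors are marked corrected with a
per-group probability. Latencies come from a rise-to-threshold race-model
sampler: a unit with rise rate ``r ~ N(μ, σ²)`` truncated positive reaches a
fixed threshold after ``threshold / r``, plus a constant onset delay; the
prosaccade (error) unit is calibrated faster than the antisaccade unit, which
reproduces the characteristic ~100 ms error-vs-correct latency gap.

Default cohort composition is 95 control / 65 MCI / 42 AD participants with
24 trials when complete; 79.2 % of participants complete all 24 and sequence
lengths never fall below 11.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .records import (
    GROUPS,
    MAX_LATENCY_MS,
    MIN_LATENCY_MS,
    OUTCOME_CORRECT,
    OUTCOME_ERROR_CORRECTED,
    OUTCOME_ERROR_UNCORRECTED,
    ParticipantRecord,
    TrialRecord,
)

GAZE_SAMPLE_INTERVAL_MS = 2.0  # 500 Hz tracker
TARGET_ECCENTRICITY_DEG = 4.0  # target appears 4 deg left/right of fixation

GAZE_CSV_COLUMNS = ("participant_id", "trial_index", "t_ms", "x_deg", "y_deg")


@dataclass(frozen=True)
class RaceParams:
    """Rise-to-threshold latency parameters.

    ``rate_mean_*`` are mean rise rates (threshold units per ms); the error
    (prosaccade) unit is faster. With the defaults the median latencies are
    ``onset_delay + threshold/rate_mean`` = 280 ms (correct) and 176 ms
    (error), matching typical correct/error antisaccade medians and a gap in
    the 90–110 ms band.
    """

    onset_delay_ms: float = 50.0
    threshold: float = 1.0
    rate_mean_correct: float = 1.0 / 230.0
    rate_mean_error: float = 1.0 / 126.0
    rate_cv: float = 0.2  # sd of the rise rate as a fraction of its mean

    def validate(self) -> None:
        for name in ("onset_delay_ms", "threshold", "rate_mean_correct",
                     "rate_mean_error"):
            if not getattr(self, name) > 0:
                raise ValueError(f"race parameter {name} must be positive")
        if self.rate_cv < 0:
            raise ValueError("rate_cv must be nonnegative")

    def rate_mean(self, outcome: str) -> float:
        return self.rate_mean_error if outcome == "error" else self.rate_mean_correct


@dataclass(frozen=True)
class GazeNoise:
    """Noise model for synthetic gaze traces: white position noise plus
    optional single-frame spikes large enough to trip the velocity filter."""

    position_sd_deg: float = 0.0
    n_spikes: int = 0
    spike_amplitude_deg: float = 6.0


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic cohort.

    ``intercept`` is the reference-group (control) intercept on the logit
    scale of the reference outcome; ``group_offsets`` are treatment-coded
    deviations. Defaults are the fitted values of the run-length
    sequential-dependence model (correct-coded): 0.741 control intercept,
    −0.200 MCI and −0.344 AD offsets, +0.047 per preceding consecutive
    success, −0.040 per preceding consecutive error, random-intercept SD
    1.374.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"control": 95, "MCI": 65, "AD": 42}
    )
    n_trials_full: int = 24
    p_full_sequence: float = 0.792
    # incomplete sequences: mass 0.8 on {21,22,23}, 0.2 on {11..20}
    p_short_high: float = 0.8
    short_high_range: tuple = (21, 23)
    short_low_range: tuple = (11, 20)
    intercept: float = 0.741
    group_offsets: dict = field(
        default_factory=lambda: {"control": 0.0, "MCI": -0.200, "AD": -0.344}
    )
    slope_success: float = 0.047
    slope_error: float = -0.040
    reference_outcome: str = "correct"  # which outcome the logit predicts
    sigma_u: float = 1.374
    correction_prob: dict = field(
        default_factory=lambda: {"control": 0.83, "MCI": 0.76, "AD": 0.72}
    )
    rt_params: RaceParams = field(default_factory=RaceParams)
    rt_mode: str = "conditional"  # "conditional" or "race"
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError("group sizes must be >= 1")
        for p in (self.p_full_sequence, self.p_short_high, *self.correction_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")
        coefs = [self.intercept, self.slope_success, self.slope_error,
                 *self.group_offsets.values()]
        if not all(math.isfinite(c) for c in coefs):
            raise ValueError("model coefficients must be finite")
        if self.reference_outcome not in ("correct", "error"):
            raise ValueError("reference_outcome must be 'correct' or 'error'")
        if self.rt_mode not in ("conditional", "race"):
            raise ValueError("rt_mode must be 'conditional' or 'race'")
        self.rt_params.validate()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "rt_params" in d:
            d["rt_params"] = RaceParams(**d["rt_params"])
        for key in ("short_high_range", "short_low_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# latency sampling
# ---------------------------------------------------------------------------

def _positive_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Draw N(mean, sd²) truncated to (0, inf) by rejection."""
    if sd == 0:
        return mean
    while True:
        r = rng.normal(mean, sd)
        if r > 0:
            return r


def simulate_race_rt(
    outcome: str, rt_params: RaceParams, rng: np.random.Generator
) -> float:
    """Sample a primary-saccade latency conditional on the trial outcome.

    The unit matching the outcome rises to threshold at rate
    ``r ~ N(μ, (cv·μ)²)`` truncated positive; latency is
    ``onset_delay + threshold/r`` clipped to the 80–700 ms analysis window.
    """
    rt_params.validate()
    if outcome not in ("correct", "error"):
        raise ValueError("outcome must be 'correct' or 'error'")
    mu = rt_params.rate_mean(outcome)
    r = _positive_normal(mu, rt_params.rate_cv * mu, rng)
    rt = rt_params.onset_delay_ms + rt_params.threshold / r
    return float(np.clip(rt, MIN_LATENCY_MS, MAX_LATENCY_MS))


def run_race(rt_params: RaceParams, rng: np.random.Generator) -> tuple[str, float]:
    """Race both units; the faster determines the outcome and the latency."""
    rt_params.validate()
    times = {}
    for outcome in ("error", "correct"):
        mu = rt_params.rate_mean(outcome)
        r = _positive_normal(mu, rt_params.rate_cv * mu, rng)
        times[outcome] = rt_params.onset_delay_ms + rt_params.threshold / r
    winner = min(times, key=times.get)
    return winner, float(np.clip(times[winner], MIN_LATENCY_MS, MAX_LATENCY_MS))


def _correction_latency(primary_ms: float, rng: np.random.Generator) -> float:
    """Corrective-saccade latency: primary latency plus a gamma-distributed
    correction interval (mean ≈ 200 ms, minimum 60 ms)."""
    return primary_ms + 60.0 + rng.gamma(4.0, 35.0)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sequence_length(config: SimConfig, rng: np.random.Generator) -> int:
    if rng.random() < config.p_full_sequence:
        return config.n_trials_full
    if rng.random() < config.p_short_high:
        lo, hi = config.short_high_range
    else:
        lo, hi = config.short_low_range
    return int(rng.integers(lo, hi + 1))


def simulate_cohort(
    config: SimConfig, return_covariates: bool = False
) -> list[ParticipantRecord] | tuple[list[ParticipantRecord], pd.DataFrame]:
    """Generate a cohort of trial sequences from a :class:`SimConfig`.

    Per-participant RNG streams are keyed by (seed, group index, member
    index), so cohort composition for existing participants is stable when a
    group size changes. With ``return_covariates=True`` the run-length
    covariates used during generation are returned alongside (for exact
    cross-checks against their post-hoc recomputation).
    """
    config.validate()
    cohort: list[ParticipantRecord] = []
    cov_rows = []
    for g_idx, group in enumerate(GROUPS):
        n_members = config.group_sizes.get(group, 0)
        for m in range(n_members):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, g_idx, m))
            )
            pid = f"{group}_{m + 1:03d}"
            u = float(rng.normal(0.0, config.sigma_u)) if config.sigma_u > 0 else 0.0
            n_trials = _sequence_length(config, rng)
            base = config.intercept + config.group_offsets[group] + u
            trials: list[TrialRecord] = []
            run_success = run_error = 0
            for j in range(1, n_trials + 1):
                target_side = "right" if rng.random() < 0.5 else "left"
                eta = (
                    base
                    + config.slope_success * run_success
                    + config.slope_error * run_error
                )
                p_ref = 1.0 / (1.0 + math.exp(-eta))
                ref_hit = rng.random() < p_ref
                if config.reference_outcome == "correct":
                    is_correct = ref_hit
                else:
                    is_correct = not ref_hit
                if config.rt_mode == "race":
                    raced_outcome, latency = run_race(config.rt_params, rng)
                    is_correct = raced_outcome == "correct"
                else:
                    latency = simulate_race_rt(
                        "correct" if is_correct else "error", config.rt_params, rng
                    )
                if is_correct:
                    outcome = OUTCOME_CORRECT
                    correction = None
                else:
                    corrected = rng.random() < config.correction_prob[group]
                    outcome = (
                        OUTCOME_ERROR_CORRECTED if corrected
                        else OUTCOME_ERROR_UNCORRECTED
                    )
                    correction = _correction_latency(latency, rng) if corrected else None
                trials.append(
                    TrialRecord(
                        index=j,
                        target_side=target_side,
                        outcome=outcome,
                        latency_ms=latency,
                        correction_latency_ms=correction,
                    )
                )
                if return_covariates:
                    cov_rows.append((pid, j, run_success, run_error))
                if is_correct:
                    run_success += 1
                    run_error = 0
                else:
                    run_error += 1
                    run_success = 0
            cohort.append(
                ParticipantRecord(id=pid, group=group, trials=trials, u=u)
            )
    if return_covariates:
        cov = pd.DataFrame(
            cov_rows,
            columns=["participant_id", "trial_index", "n_prev_success", "n_prev_fail"],
        )
        return cohort, cov
    return cohort


# ---------------------------------------------------------------------------
# gaze-trace synthesis
# ---------------------------------------------------------------------------

def _raised_cosine_step(t: np.ndarray, t0: float, duration: float,
                        x_from: float, x_to: float) -> np.ndarray:
    """Smooth position step x_from -> x_to over [t0, t0+duration] (ms)."""
    phase = np.clip((t - t0) / duration, 0.0, 1.0)
    return x_from + (x_to - x_from) * 0.5 * (1.0 - np.cos(np.pi * phase))


def simulate_gaze_trial(
    trial: TrialRecord,
    noise: GazeNoise | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Render a trial as a 500 Hz gaze-sample train (t_ms, x_deg, y_deg).

    Coordinates are degrees of visual angle, screen centre 0, rightward
    positive; time is ms from target onset. The primary saccade starts at
    ``latency_ms``, toward the target on error trials and into the opposite
    hemifield on correct trials; corrected errors get a second saccade at the
    correction latency crossing the midline. Optional Gaussian position noise
    and injected single-frame spikes (frame-to-frame velocity > 1,500 deg/s)
    provide classifier stress inputs.
    """
    if trial.outcome == "excluded":
        raise ValueError("cannot render an excluded trial")
    noise = noise or GazeNoise()
    rng = rng or np.random.default_rng(0)

    tsign = 1.0 if trial.target_side == "right" else -1.0
    ecc = TARGET_ECCENTRICITY_DEG
    primary_end = tsign * ecc if trial.is_error else -tsign * ecc

    t_stop = trial.latency_ms + 400.0
    if trial.correction_latency_ms is not None:
        t_stop = max(t_stop, trial.correction_latency_ms + 300.0)
    t = np.arange(-100.0, min(t_stop, 1900.0), GAZE_SAMPLE_INTERVAL_MS)

    x = _raised_cosine_step(t, trial.latency_ms, 40.0, 0.0, primary_end)
    if trial.outcome == OUTCOME_ERROR_CORRECTED:
        x = np.where(
            t < trial.correction_latency_ms,
            x,
            _raised_cosine_step(
                t, trial.correction_latency_ms, 56.0, primary_end, -primary_end
            ),
        )
    y = np.zeros_like(x)

    if noise.position_sd_deg > 0:
        x = x + rng.normal(0.0, noise.position_sd_deg, size=x.shape)
        y = y + rng.normal(0.0, noise.position_sd_deg, size=y.shape)
    if noise.n_spikes > 0:
        # isolated interior frames, >= 2 frames apart so spikes never merge
        candidates = np.arange(2, len(t) - 2)
        rng.shuffle(candidates)
        chosen: list[int] = []
        for c in candidates:
            if all(abs(c - k) > 2 for k in chosen):
                chosen.append(int(c))
            if len(chosen) == noise.n_spikes:
                break
        for k in chosen:
            x[k] += noise.spike_amplitude_deg

    return pd.DataFrame({"t_ms": t, "x_deg": x, "y_deg": y})


def simulate_gaze_cohort(
    cohort: list[ParticipantRecord],
    noise: GazeNoise | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Render every non-excluded trial of a cohort as one long sample table."""
    frames = []
    for p_idx, p in enumerate(cohort):
        for trial in p.trials:
            if trial.outcome == "excluded":
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, p_idx, trial.index))
            )
            df = simulate_gaze_trial(trial, noise, rng)
            df.insert(0, "trial_index", trial.index)
            df.insert(0, "participant_id", p.id)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_gaze_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False, columns=list(GAZE_CSV_COLUMNS))


def read_gaze_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GAZE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV missing columns: {sorted(missing)}")
    return df
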