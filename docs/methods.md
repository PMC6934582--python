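# Methods

## The scientific setting

Antisaccade errors — reflexive glances toward a suddenly appearing target
when the instruction is to look away — are a sensitive behavioural marker of
inhibitory control and a candidate early marker of Alzheimer's disease.
This package analyses the *sequential* structure of those errors: whether
the probability of an error on the current trial depends on the previous
trial's outcome, and cumulatively on the run of identical outcomes
preceding it, in three cohorts (healthy older controls, MCI, AD dementia).

## Trial classification

Gaze samples (500 Hz; degrees of visual angle, screen centre 0, rightward
positive, time in ms from target onset) are despiked before event detection:
a causal pass drops any frame whose displacement velocity against the last
retained frame exceeds 1,500 deg/s, and a second pass drops frames whose
velocity change exceeds 100,000 deg/s². The causal formulation is
deliberate: an isolated spike costs exactly one frame and the trace rejoins
the smooth path, whereas a symmetric central difference never sees the spike
on its own frame (it only uses the neighbours) and would instead flag the
two frames around it.

Saccades are detected with a conventional velocity/acceleration threshold
detector (30 deg/s, 8,000 deg/s², 20 ms merge window, minimum 6 ms
duration and 1° amplitude). The onset is walked back down the rising
velocity flank, so reported latencies track the movement start rather than
the threshold crossing; on noise-free traces this recovers generating
latencies to within one 2 ms sample.

Outcome labelling: the primary saccade is the first event in the 80–700 ms
window (earlier = anticipatory, absent = delayed; both excluded and never
analysed). A primary saccade toward the target is an inhibitory error; it
counts as corrected when a later event carries gaze across the midline into
the opposite hemifield (`correction_rule="crossing"`, the default). A
direction-reversal-only rule is available (`"reversal"`) for traces where
gaze reverses but never fully crosses; the crossing rule is stricter and
matches the definition of a correction as re-fixating the instructed
hemifield.

## Sequential statistics

Current-trial outcomes are binarized (corrected and uncorrected errors both
count as errors); the *previous*-trial condition keeps the three-way
distinction. Each participant's first usable trial conditions nothing —
that is forced by the definition of "previous trial". Excluded trials are
removed before pairing, so a trial following an excluded one is conditioned
on the last *usable* outcome. Run lengths ≥ 6 pool into a "6+" bin.

Contingency machinery: natural-log odds ratios with the standard
reciprocal-cell-count SE; a Haldane–Anscombe +0.5 correction (with a
warning) on zero cells; one-sample proportion Z tests with the variance at
the observed proportion (this is the variant that reproduces the published
Z family; the null-variance variant is available via `variance="null"`);
Pearson χ² with Cramér's V = √(χ²/(N·(min(r,c)−1))). No multiple-testing
adjustment is applied — comparisons are reported one at a time, matching
the per-comparison style of the tables this mirrors.

`reconstruct_total` inverts a printed (error count, 3-digit proportion)
pair to its cell total by searching round(e/p) ± 2 for an n that reproduces
the print. The inversion is exact only while e/n² > 5e-4; beyond that
several totals print identically, and the function returns the consistent
candidate nearest e/p (flagging the case where none is consistent).

## The GLMM

Response y_ij is Bernoulli with logit(p_ij) = x_ij'β + u_i and
u_i ~ N(0, σ_u²). **Response coding**: by default the linear predictor is
the logit of a *correct* response. This resolves an otherwise inconsistent
sign pattern: a positive control intercept (~0.74, i.e. P ≈ 0.68 at u = 0)
and a positive previous-success slope are coherent only if the modelled
outcome is the correct response — a control error probability near 68%
would contradict the observed ~23–44% error rates and the direction of the
predicted-probability curves. The coding is flippable
(`response_coding="error"`), and the likelihood is invariant under the flip
with negated coefficients (tested).

Fitting maximises the marginal likelihood, integrating u out per
participant with adaptive Gauss–Hermite quadrature: the integrand is
re-centred at its posterior mode (vectorised Newton across participants)
and scaled by the local curvature. With a scalar random effect 15 nodes
leave per-participant errors around 1e-8; a 202-participant log-likelihood
at 15 vs 41 nodes differs by a few 1e-6 in total, and the fit matches
`lme4::glmer(..., nAGQ=15)` to four decimals on coefficients, SEs, σ_u and
log-likelihood on a reference cohort. Optimisation is L-BFGS-B on
(β, log σ_u) starting from the in-module Newton logistic solution with
σ_u = 1; SEs come from the inverse of a central-difference observed
information at the optimum, with σ_u's SE mapped from the log scale by the
delta method. If σ̂_u falls below 0.01 the variance component is treated as
at the boundary: the model reduces to ordinary logistic regression, the
coefficients are completed by the exact Newton solve, and the fit is
flagged (never silently).

Covariates `n_prev_success` / `n_prev_fail` are mutually exclusive run
lengths (exactly one nonzero after trial 1; both zero on trial 1), the only
reading consistent with the run-length tables. Group enters
treatment-coded with control as reference; absent levels are not encoded.
Backwards selection is not automated — nested comparisons are explicit
`deviance_test` calls (2Δloglik vs χ² with df = parameter difference;
variance-component tests are boundary cases and the χ² reference is
conservative there, which is logged).

`bootstrap_sigma_ci` is a parametric bootstrap: B datasets simulated from
the fitted model, refitted (warm-started at the estimate; warm refits were
verified against cold, tight refits), percentile interval of σ̂_u. Because
the run-length covariates are outcome-derived, holding the design fixed
during simulation (the `lme4::bootMer` convention) answers a *conditional*
question and understates the unconditional sampling spread of σ̂_u
(measured: bootstrap SD ≈ 0.069 vs ≈ 0.109 across true replicate cohorts
at full scale). By default the bootstrap therefore regenerates whole trial
sequences from the fitted model — simulating each participant's outcomes
in order and recomputing the run-length covariates from the simulated
history (`regenerate="auto"`); `regenerate="fixed"` restores the
conditional convention for arbitrary fixed-effect specifications. Refit
failures are dropped and counted; more than 10% failing aborts.

`predict_average` reports P at u = 0 (the "average participant") with a
delta-method CI on the linear predictor; because the inverse logit is
monotone this equals the CI of the probability (verified against a
Monte-Carlo draw from the coefficient covariance).

## Reaction times

Kaplan–Meier survivor curves treat each trial's primary-saccade latency as
an event time (trial-level units; every analysed latency lies inside the
80–700 ms window, so censoring is structurally absent, though the estimator
accepts censor flags). The median is the smallest time with S(t) ≤ 0.5;
its CI uses the log(−log) (exponential Greenwood) transform, as implemented
by lifelines — the published tables do not state their CI method, so this
standard choice is the package's own. The Welch t test runs on natural-log
latencies with Satterthwaite df; Cohen's d uses the pooled-SD formula on
the log scale (other d variants exist and the published variant is
unstated); R² = t²/(t²+df).

## The synthetic-data generator

The generator adopts the fitted run-length model as the generative truth so
that the published coefficient table becomes a parameter-recovery target:
per-group intercepts 0.741 / 0.541 / 0.397 (control / MCI / AD, expressed
as control intercept + offsets −0.200, −0.344), slopes +0.047 per
preceding consecutive success and −0.040 per preceding failure on the
correct-coded logit, σ_u = 1.374. (The previous-outcome model variant
quotes σ_u = 1.524; both values can be set in `SimConfig`.) Error trials
are corrected with per-group probabilities 0.83 / 0.76 / 0.72, derived from
the reconstructed condition totals of the previous-trial table (631/762,
598/784, 382/533 corrected previous-error exposures); correction
probability is held constant per group — nothing published indicates a
run-history dependence.

Cohort composition follows the published completion facts: 202 participants
(95/65/42), 79.2% completing all 24 trials; incomplete lengths are drawn
with mass 0.8 on {21,22,23} and 0.2 on {11..20}, reconciling "79.2%
complete" with ">95% finished more than 20" (the implied per-cohort
expectation is 95.8%, so single seeds fluctuate around 95%; the generator
matches the stated mixture rather than forcing every seed above the
threshold).

Latencies come from a LATER-style rise-to-threshold sampler: rate
r ~ N(μ, (0.2μ)²) truncated positive, RT = 50 ms + 1/r, clipped to
[80, 700]. Rate means 1/230 ms⁻¹ (antisaccade unit) and 1/126 ms⁻¹
(prosaccade unit) put the medians at 280 and 176 ms — the published
control medians — and the error-vs-correct gap in the 90–110 ms band for
every group. By default RTs are sampled *conditional* on the logit-drawn
outcome, so the GLMM parameters remain exactly recoverable; an optional
`rt_mode="race"` lets the faster unit determine the outcome instead, which
couples outcome and latency at the cost of distorting the logistic
generating model.

Gaze rendering uses raised-cosine position profiles (40 ms primary, 56 ms
corrective saccade), optional white position noise and injected
single-frame spikes for filter tests. RNG streams are keyed by
(seed, group, member), so enlarging one group never changes existing
participants' data.

What the generator does *not* emulate: pupil or blink artifacts, drift and
calibration error, vertical gaze structure, fatigue or learning trends
within a session, and any run-history dependence of correction behaviour.
Passing tests therefore demonstrate correctness of the analysis machinery
under the stated model, not robustness to real-tracker artifacts.

## Problem sizes used in validation

Chosen to keep the default suite fast while leaving the statistics
well-powered, and stated here as the package's own design: the
parameter-recovery experiment uses 50 replicate full-size cohorts
(202 × ≤24 trials) with the bootstrap CI half-width for σ_u estimated as
the mean over the first three replicates at B = 50 each (per-seed B = 500
bootstraps would need ~25,000 refits); deviance-null calibration uses
100 replicates of 16-participant cohorts against χ²(1); bootstrap coverage
uses 20 replicates of 33-participant cohorts at B = 30. The acceptance
script re-runs the 50-cohort recovery experiment (fits only) and reports
the mean recovered σ_u.

## Known limitations

- Between-group SE columns of the published conditioning table
  (e.g. 0.259 for a contrast whose reciprocal-count SE is ≈0.247) are not
  reproducible from the standard formula and are deliberately not chased;
  only point estimates are compared.
- Published Cramér's V values appear to use a different normalisation than
  √(χ²/(N·(min(r,c)−1))); the package reports the standard definition.
- ML estimation of σ_u carries a small downward finite-sample bias
  (~3% at 202 participants), visible in the recovery experiment. The
  percentile bootstrap CI inherits that bias twice — once in the estimate
  and once by re-centring the simulation at it — so its coverage of the
  generating σ_u runs a few points below nominal (~85% rather than 95% at
  this design), a known property of percentile intervals for variance
  components.
- The classifier has no blink handling and assumes uniformly sampled,
  largely artifact-free traces apart from isolated spikes.
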