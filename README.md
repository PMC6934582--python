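# antiseq

Sequential-dependence analysis of antisaccade performance in ageing,
mild cognitive impairment (MCI) and Alzheimer's disease (AD) cohorts.

In the antisaccade task (AST) a target appears 4° left or right of fixation
and the participant must saccade to the *opposite* side; a reflexive glance
toward the target is an inhibitory error, which may or may not be followed by
a corrective saccade into the instructed hemifield. This package asks how
the outcome of the current trial depends on the recent past: the previous
trial's outcome (correct, corrected error, uncorrected error) and the run
length of consecutive identical outcomes leading up to it.

## What it computes

- **Trial classification** (`antiseq.gaze`): despiking of 500 Hz gaze
  samples (frames faster than 1,500 deg/s or 100,000 deg/s² removed),
  velocity/acceleration-threshold saccade detection, and outcome labelling
  with an 80–700 ms latency acceptance window.
- **Sequential statistics** (`antiseq.seqstats`): error counts and
  proportions conditioned on the previous trial's outcome and on run-length
  bins {1,…,5,6+}; log-odds ratios `ln(a/b) − ln(c/d)` with
  `SE = √(1/a+1/b+1/c+1/d)` and Wald Z tests; one-sample Z tests against
  chance with variance at the observed proportion; Pearson χ² with Cramér's
  V; and inversion of printed (count, rounded proportion) pairs back to cell
  totals so published tables can be re-analysed without raw data.
- **GLMM** (`antiseq.glmm`): the Bernoulli random-intercept model

  logit P(y_ij = 1 | u_i) = β₀ + u_i + β₁ x₁,ij + β₂ x₂,ij + …,
  u_i ~ N(0, σ_u²),

  fitted by maximum likelihood with adaptive Gauss–Hermite quadrature,
  with nested-model deviance tests, a parametric bootstrap CI for σ_u, and
  average-participant (u = 0) predicted probabilities.
- **Reaction times** (`antiseq.rtstats`): Kaplan–Meier survivor curves of
  saccade latency with product-limit medians and log-log CIs, and a Welch t
  test on log latency (error vs correct) with `R² = t²/(t²+df)`.
- **Synthetic cohorts** (`antiseq.synth`): a seeded generator producing
  cohorts (default 95 control / 65 MCI / 42 AD participants, ≤24 trials)
  whose outcomes follow the run-length GLMM and whose latencies come from a
  rise-to-threshold race model — so every downstream stage is testable by
  parameter recovery, and raw gaze traces can be rendered for classifier
  round-trips.

## Worked example

```sh
antiseq --mode simulate --seed 1 --out results/run1
```

simulates the default cohort, runs every analysis and writes
`table2.csv`–`table5.csv`, `glmm_fit.json` and a provenance manifest.
The fitted run-length model (from `results/run1/table3.csv`, seed 1):

| variable        | estimate (log-odds) | SE    | Z     |
|-----------------|--------------------:|------:|------:|
| intercept       | 0.783               | 0.146 | 5.37  |
| group[MCI]      | −0.225              | 0.214 | −1.05 |
| group[AD]       | −0.127              | 0.246 | −0.52 |
| n_prev_success  | 0.051               | 0.016 | 3.20  |
| n_prev_fail     | −0.028              | 0.026 | −1.09 |

with σ̂_u = 1.211 and log-likelihood −2617.96. The response is coded 1 for
a *correct* antisaccade, so the positive `n_prev_success` slope says each
additional preceding consecutive correct trial raises the odds of another
correct response by ~5%, while preceding errors lower them; the patient
group offsets are negative (more errors). The generating values were
0.741 / −0.200 / −0.344, +0.047 / −0.040 and σ_u = 1.374 — each recovered
within two standard errors. `table5.csv` for the same run shows the race
model's latency signature: e.g. control medians of 280 ms (correct) vs
179 ms (error), the characteristic ~100 ms error speed-up, in every group.

As a library:

```python
import antiseq as aq

cohort = aq.simulate_cohort(aq.SimConfig(seed=1))
df = aq.cohort_to_frame(cohort)
cov = aq.add_history_covariates(df)          # prev_outcome, run lengths
fit = aq.fit_glmm(cov)                        # adaptive-GH ML fit
print(fit.beta, fit.sigma_u)
print(aq.make_table2(df).head())              # previous-outcome conditioning
```

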