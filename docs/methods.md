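# Methods

This note documents the statistical machinery in `emanet`: the prediction
models, the time-series features, the cross-validation design, the synthetic
cohort generator, and every numerical convention that a reader re-deriving
the results would need.

## Data model

EMA responses are a long-format table: one row per scheduled prompt per
participant with a timestamp, an `answered` flag, and three integer items on
a 0–9 scale (desire to kill oneself, intent to kill oneself, ability to
resist the urge). A prompt counts as completed when at least one item is
present; features use whichever items are present. Participants with fewer
than 3 completed surveys are excluded (the boundary is inclusive: exactly 3
is retained). Compliance is completed/scheduled prompts; the scheduled count
comes from a schedule table when available and otherwise defaults to the
rows present. Timestamps are naive local time and are used for ordering
only; features never difference clock time.

## Time-series features

For each item of each participant, 24 descriptors are computed on the
completed responses in time order: `n_obs`, `mean`, `median`, `min`, `max`,
`range`, `sd`, `variance`, `coef_variation`, `skewness`, `kurtosis`, `puv`
(distinct values / responses), `prop_floor` (share of 0s), `prop_ceiling`
(share of 9s), `mssd`, `rmssd`, `mean_abs_succ_diff`, `sd_succ_diff`,
`max_change`, `pac`, `prob_increase`, `prob_decrease`, `lag1_autocorr`,
`trend_slope`. Successive differences d_t = x_{t+1} − x_t are taken between
consecutive *completed* prompts regardless of the gap between them (missing
prompts are skipped, never imputed); an optional `max_gap` argument censors
differences spanning more than a given number of scheduled prompts.
Conventions: sample (m−1) denominators for `sd`, `variance`,
`sd_succ_diff`; MSSD = Σd²/(m−1) (the variance of changes about zero);
`lag1_autocorr` is the Pearson correlation of (x_t, x_{t+1}) pairs;
`trend_slope` is the least-squares slope on completed-prompt order 0,1,….
A feature that is undefined on a series (autocorrelation of a constant
series, any successive-difference feature with fewer than two observations,
CV with mean zero) is set to 0.0 and recorded in the vector's `flags`, so
design matrices are complete while the information is not silently lost.

### Probability of acute change (PAC)

PAC is the share of successive changes that are "acute": at or above the
90th percentile (linear-interpolation quantile, inclusive comparison) of a
reference distribution of absolute changes. Two conventions are
implemented, and the difference matters:

* **own-distribution** (the default of the standalone `pac()` function):
  the reference is the participant's own changes. This makes PAC a shape
  statistic of the individual change distribution — and because the
  threshold adapts, PAC hovers near 0.10 whenever ties are rare, varying
  mainly through the tie structure of the discrete 0–9 scale. A series
  whose changes are all exactly zero scores 0 (without this rule the
  inclusive threshold would score a constant series as 1).
* **pooled** (the default of the cohort-level `DynamicFeatureExtractor`,
  learned per item in `fit`): the reference is the change distribution
  pooled over the whole sample, the convention of the acute-change
  literature this feature comes from. Against a common threshold, a
  participant who shifts by population-extreme amounts more often genuinely
  scores higher, which is the construct the feature is meant to measure and
  the version the pipeline's dynamic design uses.

Signed-change mode is available behind `change_scale="signed"`.

## Baseline design and imputation

The 20 baseline predictors are 4 behavior classes (suicidal thoughts, plan,
attempt, nonsuicidal self-injury) × 5 characteristics (lifetime presence
0/1; past-year/month/week frequency counts; self-rated future likelihood
0–4). Missing cells are completed by k-nearest-neighbor imputation (k = 5):
distance between rows is the Euclidean norm over z-scored columns observed
in both, divided by √(number of shared columns); each missing cell takes
the mean of its column over the k nearest rows that observe it, with
distance ties broken by position after a stable sort (lowest participant id
first), so imputed values are independent of row order. Rows with all 20
values missing cannot be imputed and are excluded from the baseline design
with a warning. Imputation runs inside each cross-validation fold by
default (fit on the training rows, applied to held-out rows); a
global-imputation switch exists for compatibility with pipelines that
imputed once up front.

## Elastic-net logistic regression

The solver minimizes the penalized mean negative log-likelihood given in
the README. Implementation: IRLS outer loop (probability weights floored at
1e-5) with cyclic coordinate descent and soft-thresholding on the weighted
quadratic approximation; an active-set pass over nonzero coordinates
precedes each full sweep. Predictors are z-scored internally (unit sample
variance, ddof = 1); returned coefficients are back-transformed, and the
standardized-scale coefficients are retained for penalties, KKT checks, and
importance. Zero-variance columns are dropped with a warning and report
zero coefficients. Convergence: maximum absolute coefficient change below
1e-7 (configurable) between sweeps, cap 1e5 sweeps; exhausting the cap
raises an error carrying the last iterate. A step-halving safeguard keeps
the penalized objective non-increasing across outer iterations, since the
unguarded quadratic approximation is not strictly monotone. Coefficients
smaller than 1e-12 after convergence are snapped to exact zero so that
λ ≥ λ_max yields an exactly-null model whose constant predictions are
treated as ties downstream (AUC exactly 0.5), rather than float dust
producing noise rankings. λ_max = max_j |(1/n) Σ x_ij (y_i − ȳ)| / α on
standardized predictors; for α = 0 the conventional surrogate evaluates the
formula at α = 0.001. Paths are log-spaced descending and warm-started.
Classification uses threshold 0.5, inclusive (p = 0.5 is positive). The
inner loops are numba-compiled; results are identical to the pure-Python
path at tolerance.

## Cross-validation and selection

Folds are stratified by outcome (per-fold positive counts differ by at most
one) with seeded shuffling; with ~9 events among 83 participants,
unstratified splits would regularly produce folds without a single positive
case. Schemes: 5×3 (default), 10×3, leave-one-out. For every resample the
full (α, λ) grid is fit on the training portion — standardization and, for
the baseline design, imputation happen inside the fold — and scored on the
held-out portion; the pair maximizing mean held-out AUC wins (accuracy
available behind a switch), with ties broken toward the largest λ, then the
largest α, preferring sparsity. Default grid: α ∈ {0, 0.1, …, 1.0} × 50
λ values down to ratio 0.05 of λ_max (p can exceed n). The winning pair's
held-out metric distribution is reported (mean and 25th–75th percentile
IQR), and the final model refits all data at that pair. Reporting
performance from the resamples used for selection is mildly optimistic;
that is the convention mirrored here, stated rather than hidden. Undefined
metrics on a fold (single-class AUC, PPV with no predicted positives) carry
flags; summaries either drop them (default) or count them as zero. PPV with
zero predicted positives is reported as 0.0 so fold distributions can
legitimately contain exact zeros. Variable importance is
100·|β_j|/max_k|β_k| on the standardized scale, signs reported alongside —
invariant to rescaling any original predictor column.

## Synthetic cohort generator

The generator emulates the structure of an inpatient EMA study so every
stage is testable without participant data. Per participant: length of stay
lognormal (log-mean 1.6926, log-SD 0.6912 ≈ mean 6.9, SD 5.4 days)
truncated to [2, 46]; 4 or 6 prompts/day (assigned with probability 45/104
of the lower rate, mirroring a two-wave design), evenly spaced in a 12-hour
waking window (optional jitter, off by default). Latent ideation follows a
mean-reverting AR(1) with transient jumps,

    x_t = μᵢ + φ(x_{t−1} − μᵢ) + σᵢ ε_t + J_t,   x₀ = μᵢ (stationary start),

with φ = 0.5, μᵢ ~ N(3.0, 1.8) clipped to [0, 9], σᵢ ~ Gamma(2.0, rate 3.3)
(mean 0.61 — calm baselines against which jumps register as acute shifts),
jump probability πᵢ ~ Beta(1.5, 8.5) per prompt, jump magnitude
Uniform(3, 6) with random sign. Items observe x_t with N(0, 0.5) noise,
rounded and clipped: desire directly, intent from an attenuated copy
(0.8·x_t), resist-urge from the reversed scale 9 − x_t. Nonresponse is
logistic in latent severity and a person factor,
P(miss) = σ(δ₀ + δ_sev·x_t + δ_p·uᵢ) with (δ₀, δ_sev, δ_p) =
(−0.55, 0.12, 1.0) — severity-linked, hence MNAR-capable — and uᵢ is a
mixture: N(0,1) with probability 0.78, shifted by +3 with probability 0.22
to model a disengaged subgroup that never adopts the protocol. These values
were chosen to match the published compliance summaries of the study design
being emulated (mean ≈ 52%, SD ≈ 19, range ≈ 8–96%, retention ≈ 80%);
simulated cohorts give ≈ 50% mean compliance and ≈ 84% retention. The
outcome follows

    P(attempt) = σ(γ₀ + γ_jump·πᵢ + γ_mean·μᵢ + γ_nc·(1 − complianceᵢ)),

defaults (γ_jump, γ_mean, γ_nc) = (8, 0.35, 2), with γ₀ calibrated by
Monte-Carlo root-finding (Brent's method on 10,000 simulated participants,
conditioning on the ≥3-surveys inclusion rule) so the expected event rate
among analyzed participants hits the 10.8% target within ±0.005. Baseline
predictors are noisy monotone transforms of μᵢ with a shared per-person
reporting distortion (N(0, 2)) added before the item transforms —
retrospective self-report error is a property of the respondent, so
averaging 20 items cannot undo it, keeping the baseline design informative
but clearly weaker than direct EMA measurement. One participant per cohort
skips the baseline survey entirely, and 2.16% of baseline cells are
missing at random. One RNG stream per participant is spawned from the
master seed, so cohorts are bit-reproducible and stable under reordering.

### What the generator does not emulate

Diagnoses and demographics; within-day timing effects; autocorrelated
nonresponse; item-level (as opposed to prompt-level) missingness; any
feedback from responses to later prompts. The within-person autocorrelation
and variance decomposition of real inpatient ideation are not published, so
φ and the volatility distribution are plausible choices, not fits. Passing
simulation tests therefore demonstrates that the pipeline recovers the
structure it assumes, not that real EMA data contain that structure.

## Simulation studies

Three seeded studies double as the package's validation suite
(`emanet.experiments`; run by `scripts/acceptance.py` and the acceptance
tests). All use a compact grid (α ∈ {0.1, 0.55, 1.0} × 30 λ) and 5×6
cross-validation so ten replications finish in minutes on one CPU; problem
sizes are 366 enrolled (~300 analyzed) for the ordering study and 245
enrolled (~200 analyzed) for the others.

* **Planted-signal recovery.** Outcomes are made jump-driven:
  (γ_jump, γ_mean, γ_nc) = (20, 0.6, 0) — the noncompliance channel is off
  because no primary design observes compliance, so it would only add
  unexplainable outcome noise. Expected: mean CV AUC ordering
  dynamic > mean > baseline with both gaps > 0.03 in ≥ 8 of 10 seeds, and a
  PAC feature among the dynamic model's top-10 importances in ≥ 8 of 10.
  The ordering holds in 8/10 seeds. PAC prominence reaches only ~4–5/10:
  on a clipped 0–9 integer scale every magnitude feature (sd, variance,
  MSSD, RMSSD, max change) is inflated by the same jumps PAC counts, and
  clipped downward jumps fall below the pooled acute-change threshold while
  still feeding the magnitude features, so PAC is never the uniquely
  strongest jump-propensity proxy and its inclusion in the sparse final
  model is close to a coin flip among highly correlated instability
  features. This limitation is structural to the generative family, not a
  solver artifact, and the corresponding check is left failing rather than
  weakened.
* **Missingness effect.** Under the default generator (γ_nc = 2), adding
  the compliance predictor raises the mean model's mean CV AUC (paired over
  10 seeds). For the dynamic model the gain is ~0: the `n_obs` features
  already encode completed-prompt counts, so the dynamic design observes
  missingness before compliance is appended — an intrinsic redundancy of a
  feature set that includes the number of observations.
* **Null control.** With outcomes shuffled, all three models' mean CV AUC
  stays within 0.1 of 0.5. The residual upward drift (~0.05–0.09) is the
  documented selection optimism of reporting performance at the
  grid-selected pair.

## Limitations

Performance estimates share resamples with hyperparameter selection
(optimistic; nested CV would be the honest alternative and is the natural
extension). The per-seed noise of a mean CV AUC at ~25 events is ±0.04–0.05,
so ordering checks with 0.03 gaps operate at the edge of resolution. The
identity of the 16 unnamed features of the emulated 24-feature set cannot be
verified, so feature-set equivalence with the original analysis is not
claimed. No calibration assessment beyond the Brier score, no decision-curve
analysis, and no significance testing between models is provided.
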