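# emanet

Dynamic time-series features of momentary suicidal thinking, and elastic-net
prediction of short-term post-discharge suicide attempts, for intensive
longitudinal (EMA) studies of psychiatric inpatients.

## The problem

Psychiatric hospitalization is followed by a sharply elevated risk of suicide
attempt in the first weeks after discharge, yet risk prediction usually relies
on baseline interviews taken once at admission. Smartphone-based ecological
momentary assessment (EMA) can instead sample suicidal thinking several times
a day during the stay: three items — desire to kill oneself, intent to kill
oneself, and ability to resist the urge — each rated 0 (none) to 9 (very
much). This package implements the full analysis chain that asks whether the
*dynamics* of those ratings (how unstable they are, how often they shift
acutely) predict a post-discharge attempt better than their average level or
than baseline history, in cohorts where the outcome is rare (~10% base rate).

Three nested designs are compared with penalized logistic regression:

* **baseline** — 20 self-injurious-thoughts-and-behaviors history predictors
  (4 behaviors × lifetime presence, past-year/month/week frequency, future
  likelihood 0–4), sporadic missingness completed by k-nearest-neighbor
  imputation;
* **mean** — the mean of each EMA item (3 predictors);
* **dynamic** — 24 time-series features per item (72 predictors): location,
  spread, shape, instability (MSSD, RMSSD, successive-difference summaries,
  maximum change, probability of acute change) and temporal structure;

plus secondary variants that append percentage compliance, treating
*informative missingness* as a predictor in its own right.

The model is the elastic net: minimize

    -(1/n) Σᵢ [ yᵢ log pᵢ + (1-yᵢ) log(1-pᵢ) ]
        + λ [ (1-α)/2 ‖β‖₂² + α ‖β‖₁ ],   pᵢ = σ(β₀ + xᵢᵀβ)

fit by cyclic coordinate descent with soft-thresholding on an IRLS quadratic
approximation, predictors z-scored internally, intercept unpenalized, warm
starts along a log-spaced λ path. (λ, α) are chosen by repeated stratified
k-fold cross-validation (5×3 by default; 10×3 and leave-one-out supported)
maximizing mean held-out AUC, and performance is summarized per resample with
a rare-event metric suite: AUC, AUPRC, accuracy, PPV, sensitivity,
specificity, Brier score, Cohen's κ (classification threshold 0.5,
inclusive). Predictor importance is |standardized coefficient| scaled 0–100.

Because no participant-level data are public, the package ships a
first-class synthetic cohort generator that emulates the study's structure —
lognormal 2–46-day stays, 4–6 prompts/day, ~50% compliance with
severity-linked (MNAR) nonresponse and a disengaged subgroup, mean-reverting
AR(1) ideation with transient jumps, and an outcome model whose logit loads
on jump propensity, mean severity, and noncompliance — with all latent
parameters retained so planted signal can be verified end to end.

## Worked example

```python
from emanet import (CohortConfig, calibrate_intercept, generate_cohort,
                    make_design, cross_validate, CvScheme)

config = calibrate_intercept(CohortConfig(n_participants=104, seed=3))
cohort = generate_cohort(config)
design = make_design(cohort, "dynamic")        # participants x 72 features
report = cross_validate(design, CvScheme(n_folds=5, n_repeats=3, seed=3))
print(round(report.mean["auc"], 3), round(report.selected_lambda, 4),
      report.selected_alpha)
print(report.importance.head(3)[["importance", "sign"]])
```

On this seed the simulated cohort retains 88 of 104 enrolled participants
(84.6% retention, 9.1% attempt rate, mean compliance 50.0%) and the snippet
prints

```
0.704 0.0262 0.7
                          importance  sign
predictor
desire__pac               100.000000    -1
intent__prob_decrease      98.697426     1
resist_urge__trend_slope   87.477584    -1
```

mean cross-validated AUC 0.704 for the dynamic design at the selected
(λ = 0.026, α = 0.7), with dynamics — the acute-change probability of desire,
the share of decreasing intent steps, the trend in ability to resist — rather
than levels carrying the largest standardized coefficients. The same run from
the shell:

```
emanet report --seed 3 --model dynamic --cv 5x3 --out run3
```

writes `report.json` (per-resample metrics, means and IQRs, selected
hyperparameters, importance table) plus a tidy `fold_metrics.csv` for violin
plots, and a copy of the resolved configuration for exact reruns.

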