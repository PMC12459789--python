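# Methods

This note documents the models, defaults and design choices behind
`bioagekit`, and what the synthetic validation does and does not show.

## 1. The estimand and the modeling pipeline

The regression target is **residual life**: the time between a health
examination and the examinee's death, computed as calendar days divided
by 365.25. Only records with an observed death carry a target, so the
modeling cohort is deceased-only; every examination visit is treated as
an independent instance (no per-person deduplication).

Cohort construction applies, in order: (1) record exclusions —
accidental deaths (a configurable cause-of-death label set), records
under 20 years of age at exam (strictly `age < 20`; exactly 20 is
retained), and long-term-medication users (a configurable flag column);
(2) removal of features whose missing rate is *strictly* above 90%
(questionnaire items can be almost entirely blank); (3) the
deceased-only filter; (4) target computation. Each step logs counts so
input rows always equal output rows plus removals.

The regressor is LightGBM (leaf-wise gradient-boosted trees), wrapped
in a scikit-learn estimator. Sexes are always modeled separately.
Published per-sex hyperparameter settings for the imputed and filtered
datasets ship verbatim as presets (`paper-mice-male`, `paper-mice-female`,
`paper-filtered-male`, `paper-filtered-female`); they target cohorts of
~10⁴ records with several hundred features, so the default preset for
synthetic work is lighter (500 trees, 63 leaves, learning rate 0.05,
early stopping after 50 rounds without validation-R² improvement).
One preset stores `num_leaves = 3130` with `max_depth = 11`, more leaves
than a depth-11 tree can hold; LightGBM accepts this (the depth cap
binds) and the value is kept as published. Early stopping monitors R²
on the validation set through a custom evaluation hook. A deterministic
mode (single thread, `deterministic=true`, row-wise histograms) is the
default so that fixed seeds reproduce fits bit-for-bit.

Data are split 80/10/10, stratified on coarse age bins (20–40, 41–60,
61–120) so the age mix is consistent across splits; a bin with fewer
than three rows triggers a warning and an unstratified best-effort
split. Evaluation reports R², MAE, MSE, RMSE (computed from the
textbook formulas, not a library call, and cross-checked against one in
the tests) plus the SD of the actuals; zero variance in the actuals is
flagged explicitly instead of propagating NaN.

## 2. Biological-age conversion

`BioAge = AvgAge − predicted residual life`, where `AvgAge` is the
average life expectancy for the record's region, year and sex. The
packaged table transcribes the Taiwanese per-city values for ROC year
111 (= Gregorian 2022; conversion happens at load, values are stored
against Gregorian years): 22 cities/counties plus the national row,
each with total/male/female columns. Queries with no exact (region,
year) row — e.g. Matsu, which the published series omits, or years
outside it — fall back to the latest national value for the requested
sex, and the result carries a source tag (`exact-lookup` /
`national-fallback`). Negative biological ages are possible for very
long predicted residual life and are flagged, not clamped. Synthetic
cohorts are region-less and use a constant configured `AvgAge` so the
conversion is exercised without pretending regional realism.

## 3. Survival validation

Individuals are grouped by `BioAge − ChronAge` with a ±2.5-year Stable
band (the boundary belongs to Stable). Kaplan-Meier curves are
estimated per group from the observed residual lives, with time zero at
the exam. The estimator and the k-group log-rank test are implemented
from first principles and cross-checked against `lifelines` to 1e-8 in
the tests. Conventions: the step function is right-continuous (the
factor for deaths at t applies from t onward); tied deaths aggregate
into one factor; subjects censored exactly at a death time remain at
risk for that time. A deceased-only cohort has no censoring, but both
functions accept censoring flags so follow-up-truncated subjects can be
analysed. The ordering report evaluates
`Ŝ_Young ≥ Ŝ_Stable ≥ Ŝ_Aging` on a 0.1-year grid from 0 to the last
event time (ties count as ordered) and flags any group with fewer than
80 subjects, since small groups make the curves unstable.

## 4. Imputation

`ChainedImputer` implements chained equations: an initial mean fill
(modal level for categoricals, ties resolved by level order), then a
fixed number of cycles (default 5) in which each incomplete feature in
turn is reset to missing, a model is fitted on the remaining features
over the rows where it is observed, and the missing cells are
re-predicted. Features are visited in ascending missing-rate order.
The per-feature model family is a random forest by default (12 trees,
depth 8, 60% bootstrap subsample — chosen as the family used by
forest-based chained-equation implementations), with a ridge/logistic
fallback below 30 observed rows and a marginal fill below 5; a single
CART and a pure linear family are available for speed. The final
cycle's models are retained, so validation/test tables are completed
*from training-set models*; a feature that is missing in new data but
was never missing in training has no model, and a supplementary model
is fitted on the completed training table on demand (recorded on the
estimator). Observed cells are never altered; the regression target is
never among the imputer's inputs, which avoids target leakage; the
imputer is fitted after the split, on the training rows only, and
per sex in the pipeline.

The rule-based alternative drops features with a missing rate strictly
above 2% and then every row still containing a missing value.

## 5. Interpretation and intervention

Biomarker nomination ranks features by **average split gain** (total
gain divided by split count) in the fitted ensemble. Per-record
attributions use the exact tree-path Shapley algorithm built into
LightGBM (`pred_contrib`); the base value is the mean training
prediction and additivity `φ₀ + Σ φᵢ = ŷ` is asserted to 1e-6 on every
explained record. "Life-shortening" means a negative contribution on
the residual-life scale.

Pearson correlations are computed from the completed *training* table
(avoiding test leakage) over continuous features only; a categorical
feature nominated among a record's top-3 factors is reset to its modal
level and its partner search is skipped, with a flag on the result.
Zero-variance features get undefined (missing) coefficients with a
warning. Partner and tie ordering is deterministic (by |r|, then name).

The intervention resets the union of a record's top-3 life-shortening
features and each continuous factor's three most correlated partners
(every feature modified once) to reference means, then re-predicts.
Reference means default to the same-sex, same-10-year-age-bin training
mean — the more specific of the two natural choices — with a
`granularity="global"` switch. Demographic columns (`chronological_age`,
`sex`) are never nominated as factors nor reset: age is not a
modifiable biomarker, and "resetting" it to an age-bin mean is
meaningless. The change in predicted residual life is categorised with
a 0.5-year band: strictly within ±0.5 is *unchanged*, at or beyond the
band *improved*/*worsened* by sign.

## 6. The synthetic cohort generator

The generator emulates the structure the pipeline assumes, with a fully
known mortality model so recovery is testable. Per person: latent
feature z-scores drawn block-diagonally (equicorrelation ρ, default
0.3, within each of the laboratory / anthropometry / questionnaire
blocks; the joint distribution of real screening features is unknown,
so this structure is a modelling choice, not an inference); age at
death

```
death_age = baseline_life_expectancy + Σ_f effect_f · z_f
            + categorical offsets + N(0, noise_sd²),
```

truncated below at the last exam age plus a small ε so residual life
stays positive. Measured values are the person latent plus per-visit
jitter (SD 0.1). Death dates after the 2018-11-30 follow-up cutoff are
blanked (alive at tracking end). Subpopulations: under-20 examinees
(survival unrelated to the signal model — they are excluded upstream
anyway), long-term-medication flags, and accidental deaths whose death
time is brought forward by an exponential deduction (mean 5 y), which
makes the accidental-death exclusion rule empirically consequential:
including those records measurably degrades held-out fit on natural
deaths. Missingness is injected per block (plus per-feature overrides
that push questionnaire items past the 90% cutoff) with exact-count
masking, so realised rates match targets to rounding; MAR mode makes
laboratory missingness rise with age decile at the same overall rate.
Categoricals have 2–5 levels and, by default, no survival effect
(they are excluded from correlation partnering downstream).

**Selection effects and the standard validation cohort.** Two
truncation artifacts shape any deceased-only design and had to be
designed around, not ignored. *Right truncation*: with late exam dates,
the records that survive the deceased-only filter are disproportionately
early deaths. *Left truncation*: conditional on being alive at exam age
a, expected death age increases with a — an 85-year-old cannot die at
80 — so across a wide exam-age range predicted death age tracks
attained age, and `BioAge − ChronAge` degenerates into a (reversed) age
ranking rather than a frailty measure. The standard validation cohort
is therefore an **age-banded retrospective cohort**: ~7,200 single-visit
male-analogue persons examined at ages 66–74 in 1998–2005 (≈5,000
modeling records after exclusions), 50 continuous features of which 10
carry effects of ±1.5–3 years/SD, noise SD 2 years, baseline life
expectancy 80. Age-matching isolates the feature-driven frailty signal
that biological age is meant to capture; it is the synthetic analogue
of validating a biomarker in an age-homogeneous panel. The cohort is
single-sex because the generator attaches no sex-specific survival
effect and the pipeline always models sexes separately — a mixed cohort
would only halve the per-model sample; the two-sex path is exercised by
the pipeline tests and the packaged demo.

A related consequence: with a wide exam-age window, residual life
inherits the exam-age variance, so a single feature can never dominate
its correlation structure regardless of effect size. Tests that probe
the generator's signal mechanics therefore use narrow exam-age bands,
where the stated effect sizes imply near-deterministic correlations.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: realistic clinical marginal distributions
(features are standard normal latents, not lab units), longitudinal
within-person biomarker trajectories, informative censoring,
non-linear or interacting hazards, and regional/temporal life-expectancy
structure. Results on the synthetic cohort demonstrate that the
pipeline recovers what it is designed to recover under its own
assumptions, not that those assumptions hold in any particular
screening population.

## 7. Problem sizes and numerical choices

Test and validation runs use: the ~5,000-record standard cohort (one
shared pass: imputation ≈ 2 min of the suite's ≈ 2.5-minute total);
n = 2,000 tables for imputation-quality checks (3 seeds); 5 seeds of
the standard cohort, generated complete, for gain-ranking recovery
(imputation is orthogonal to that property); 1,000 null replicates for
log-rank calibration. Residual life uses 365.25-day years everywhere.
Cutoffs on missing rates are strict inequalities. Degenerate inputs
(empty cohorts, all-censored tables, zero-variance actuals, features
100% missing) raise explicit errors or flags rather than NaNs.
Determinism: every stochastic component takes a seed; the pipeline fans
a global seed out per stage via SHA-256, and a deterministic replay
reproduces artifact digests byte-for-byte.

## 8. Known limitations

- The metric's validation is indirect (group survival separation);
  nothing here establishes clinical validity of any biological-age
  number for an individual.
- Deceased-only training estimates E[residual life | features, death
  observed], which differs from the population quantity whenever
  follow-up truncation binds; the age-banded design controls but does
  not eliminate this.
- The intervention is a model counterfactual: it shows what the fitted
  model predicts if features moved, not what a physiological
  intervention would achieve; correlated-partner resets inherit any
  confounding the correlation matrix encodes.
- Pearson partnering is linear and continuous-only; categorical
  relationships are not exploited.
- The packaged life-expectancy table covers one published year; other
  years require a user-supplied file with the same schema.
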