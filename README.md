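# bioagekit

Biological-age estimation from health-examination records via
residual-lifespan regression — with synthetic cohort generation,
chained-equations imputation, Kaplan-Meier validation and a
counterfactual "what-if" intervention experiment.

## The problem

Chronological age counts years since birth; *biological age* tries to
measure how far a body has actually aged. Given a health-examination
record (questionnaire answers, anthropometry, laboratory results) and
mortality follow-up, the package

1. regresses the **residual life** observed between an examination and
   death on the exam features with gradient-boosted trees (LightGBM,
   leaf-wise growth), and
2. converts the prediction to a biological age against a
   government-published life-expectancy table:

   ```
   BioAge = AvgAge(region, year, sex) − ResidualLife_predicted
   ```

Because no ground truth for biological age exists, the metric is
validated indirectly: test individuals are split into **Aging**
(`BioAge > ChronAge + 2.5`), **Stable** (`|BioAge − ChronAge| ≤ 2.5`) and
**Young** (`BioAge < ChronAge − 2.5`) groups, Kaplan-Meier survival
curves `Ŝ(t) = Π (1 − dᵢ/nᵢ)` are estimated per group, and a log-rank
test checks that a valid metric orders them Young ≥ Stable ≥ Aging.

For interpretation, each prediction is decomposed into exact additive
(Shapley) feature contributions `ŷ = φ₀ + Σ φᵢ`; the top life-shortening
features of a record, together with their most Pearson-correlated
partners, are reset to reference (same-sex, same-age-band) means and the
record re-predicted — a change below 0.5 years counts as unchanged.

Real cohorts of this kind are licensed and cannot be shipped, so the
package includes a first-class synthetic cohort generator with a fully
known mortality model (feature-dependent death times), which makes every
stage of the pipeline testable end to end.

## Worked example

```python
>>> import bioagekit as bk
>>> table = bk.load_life_expectancy()          # packaged Taiwanese table, ROC year 111
>>> table.lookup("Taipei", 111, "male")
(80.55, 'exact-lookup')
>>> bk.to_biological_age(75, 15)               # residual life 15 y where AvgAge = 75
60.0
```

A 55-year-old predicted to live 15 more years in a region whose average
life expectancy is 75 would reach 70 — five years short of the norm —
so their biological age is 60.

Full pipeline on a synthetic two-sex cohort (2,000 persons, exams at
ages 66–74 in 1998–2005, three causal biomarkers, block missingness):

```bash
bioage-pipeline run --config examples/demo.yaml --out runs/demo
```

The run writes per-stage artifacts, `results.json`, `report.md` and
plots. On this demo (seed 7) the male stratum prints:

```
R² = 0.5222   MAE = 2.298 y          (test set, n = 88)
groups: Young 10 / Stable 67 / Aging 11
log-rank χ² = 7.80 (df 2), p = 0.020
intervention: improved 52.3% / unchanged 19.3% / worsened 28.4%
```

i.e. the model explains half of the residual-life variance, the
survival curves separate significantly (groups this small — the report
flags any group under 80 subjects — keep the ordering noisy), and
resetting each record's top-3 life-shortening biomarkers plus their
correlated partners to reference means would lengthen the predicted
residual life of half the cohort. Larger cohorts sharpen all three
results (see `tests/test_acceptance.py`, which uses the standard ~5,000
record validation cohort: R² ≈ 0.7, ordering fraction ≥ 0.9,
log-rank p < 0.001, improved fraction > 0.5).

## Layout

| module | contents |
|---|---|
| `bioagekit.simulate` | synthetic cohorts with known mortality model |
| `bioagekit.cohort` | merge + exclusion rules + residual-life target |
| `bioagekit.impute` | `ChainedImputer` (MICE-style) and rule-based filtering |
| `bioagekit.model` | stratified split, `ResidualLifeRegressor`, metrics |
| `bioagekit.lifetable` | life-expectancy lookup and BioAge conversion |
| `bioagekit.survival` | grouping, Kaplan-Meier, log-rank, ordering report |
| `bioagekit.interpret` | gain ranking, SHAP attributions, PCC, interventions |
| `bioagekit.pipeline` / `cli` | config-driven runner, manifests, reports |

See `docs/methods.md` for the modelling assumptions, parameter
defaults and known limitations.
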