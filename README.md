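# crossage

Simulation and evaluation toolkit for cross-sectional biological-age
predictors. The package studies what happens when per-subject "aging
divergence" (the age-independent part of biological age) is estimated from
markers that were weighted purely by their association with chronological
age — and how the resulting predictions relate to simulated truth and to
prospective mortality.

## What's inside

- `crossage.synthgen` — synthetic cohort generators:
  - a true-marker / false-marker pair that is observationally
    indistinguishable but differs in its relation to the latent divergence;
  - four three-marker scenario cohorts (A–D) with identical observable
    moments but varying divergence loadings;
  - a high-dimensional survival cohort (Gompertz mortality on the age
    timescale, left truncation at baseline age, administrative censoring)
    calibrated by numerical quadrature to a target event fraction.
- `crossage.predictors` — age-predictor families (OLS, cross-validated
  ridge, first principal component, Klemera-Doubal-style precision-weighted
  reversed regressions, sign-preserving equal and random weights), Bonferroni
  marker pre-selection, and divergence extraction as residual-on-age.
- `crossage.evaluation` — truth-recovery metrics, age RMSE, Cox
  proportional-hazards association of the scaled divergence prediction with
  mortality (left-truncated, sex-adjusted, Efron ties), observational
  moment-equivalence diagnostics, and random-weight coefficient summaries.
- `crossage.pipeline` / `crossage.cli` — reproducible end-to-end experiments
  with config hashing and seed bookkeeping.

## CLI

```bash
# write a synthetic cohort CSV
crossage simulate --kind example1 --seed 1 --out cohort.csv
crossage simulate --kind lls --seed 1 --out lls.csv

# four-scenario truth-recovery comparison (results.csv / summary.csv / meta.json)
crossage scenario-experiment --replicates 20 --seed 1 --out out/scenario

# survival-cohort contrast: ridge vs OLS-on-preselected vs equal vs random
crossage cohort-experiment --n-draws 1000 --seed 1 --out out/cohort

# score one method's truth recovery on a cohort CSV with a delta column
crossage evaluate --cohort cohort.csv --method mlr --out metrics.json
```

Cohort CSVs use one row per subject with columns `id, age` plus optional
`sex, entry_age, exit_age, event`, marker columns, and optional truth
columns `delta, bioage, lambda`. Generator parameters can be supplied as a
YAML mapping via `--config`.

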