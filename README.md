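# mrmediate

Two-sample Mendelian randomization (MR) from GWAS summary statistics, with
multivariable adjustment and two-step mediation analysis, plus a synthetic
summary-statistics simulator so the whole pipeline is testable offline.

## What it does

* **`summary_data`** — read/write a tab-separated GWAS summary-statistics
  dialect, select genome-wide-significant instruments, greedily LD-clump
  them against a user-supplied r² matrix, compute instrument-strength
  F statistics (`F = R²(N−K−1)/[K(1−R²)]`, per-variant
  `R² = 2·eaf·(1−eaf)·β²`), and harmonize exposure/outcome pairs (dropping
  palindromic, outcome-significant, missing and allele-mismatched variants
  with a full audit trail).
* **`estimators`** — inverse-variance-weighted (multiplicative random
  effects, under-dispersion floored), Egger regression (slope + intercept),
  weighted median, simple/weighted mode, Wald ratio, and odds-ratio
  conversion.
* **`sensitivity`** — Cochran's Q, the Egger intercept pleiotropy test, a
  simulation-based outlier detection/correction procedure (global RSS test,
  per-variant outlier test, corrected estimate, distortion test), and
  leave-one-out influence analysis.
* **`mvmr`** — multivariable IVW over the union of per-exposure instruments.
* **`mediation`** — two-step mediator screening with Benjamini–Hochberg
  adjustment per step, delta-method indirect effects (`β1·β2`), mediation
  proportions (`100·β1·β2/β`), and the significant/suggestive tiering.
* **`synthetic`** — a seeded generator for exposure/mediator/outcome GWAS
  tables under a linear structural model (instrument effects, sampling
  noise scaled by allele frequency and sample size, optional pleiotropy and
  LD blocks), plus a packaged 69-row benchmark table of published two-step
  mediation estimates used for regression-testing the arithmetic.
* **`pipeline` / `cli`** — a two-stage driver configured by YAML.

## CLI

```sh
# generate a synthetic scenario (writes TSVs, an LD matrix, and a ready config)
mrmediate simulate --config scenario.yaml --out data/

# stage 1: bidirectional univariable MR + sensitivity battery + optional MVMR
mrmediate stage1 --config data/config.yaml --out results/ --seed 1

# stage 2: two-step mediation over the configured mediator panel
mrmediate stage2 --config data/config.yaml --out results/ --seed 1
```

A scenario config looks like:

```yaml
scenario:
  seed: 5
  beta_total: 0.1424       # log-odds exposure->outcome effect
  j_instruments: 30
  j_outcome_instruments: 30
  mediators:
    - {name: m1, a: 0.12, b: 0.2, j_instruments: 25}
```

The run config written by `simulate` lists the exposure/outcome/mediator
TSV paths, optional `covariates` (for multivariable adjustment), the LD
matrix, thresholds and seeds; see `mrmediate.pipeline.RunConfig`.

All stochastic components (bootstrap SEs, outlier-test simulations,
scenario generation) take explicit seeds; re-running with the same config
and seed produces byte-identical output tables.

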