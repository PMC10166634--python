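# previndex

Complete cancer prevalence estimation from limited-duration registry
observations via completeness indexes, with a registry microsimulator for
end-to-end validation.

Cancer registries can only observe prevalence back to the start of
registration; survivors diagnosed earlier are missed. The completeness
index R at duration *d* is the ratio of *d*-year limited-duration prevalence
to complete prevalence, so complete prevalence is estimated as
`N_d / R_d`. This package implements:

- **Counting method** (`previndex.counting`): limited-duration prevalence at
  an index date, with patients lost to follow-up weighted by their cohort's
  actuarial annual survival probabilities (stratified by sex, age band at
  diagnosis, site and 5-year period, with deterministic pooled fallbacks).
- **Model-based R-indexes** (`previndex.survival`, `previndex.incidence`,
  `previndex.completeness`): Ederer-2 cohort relative survival, Weibull
  mixture-cure model fitting by weighted nonlinear least squares, logistic
  age-cohort incidence models (log-linear or degree-6 polynomial age on the
  logit scale, nonparametric 10-year birth-cohort effects, AIC comparison),
  combined into R-indexes by reconstructing prevalent mass over a lifelong
  yearly lookback.
- **Empirical R-indexes**: ratios of observed prevalent counts from
  long-series registries, `R = N(≤d) / N(≤35)`.
- **External R-indexes**: pre-computed index tables loaded from CSV, usable
  interchangeably.
- **Microsimulator** (`previndex.simulate`): individual-level synthetic
  registries with known generative truth (logistic age-cohort incidence,
  mixture-cure survival, life-table background mortality, exponential loss
  to follow-up) plus brute-force complete-prevalence oracles. A scenario
  library ships four contrasting sites: late-onset/low-survival,
  late-onset/high-survival, early-onset/high-survival, and bimodal.
- **Validation statistics** (`previndex.validation`): APRD (absolute,
  case-share weighted) for truncation validation and signed,
  population-weighted PRD for method comparison by registration-length
  group.

## CLI

The `previndex` command wires the stages together:

```sh
previndex simulate --scenario breast_like --registration-start 1990 \
    --seed 1 --out-dir out/
previndex count-prevalence --registry out/registry.csv --out out/prev.csv
previndex fit-survival --registry out/registry.csv \
    --life-table out/life_table.csv --out out/cure.json
previndex fit-incidence --registry out/registry.csv \
    --population out/population.csv --year-start 1990 --year-end 2012 \
    --out out/incidence.json
previndex build-index model --incidence-params out/incidence.json \
    --cure-params out/cure.json --life-table out/life_table.csv \
    --out out/index.csv
previndex estimate-complete --prevalence out/prev.csv \
    --index-csv out/index.csv --out out/complete.csv
previndex run-all --config config.yaml --out-dir out/
```

`run-all` runs the full experiment from a YAML config (see
`tests/test_pipeline.py` for a minimal example): simulate estimation /
validation / comparison registries, count prevalence, fit models, build
model-based and empirical indexes, estimate complete prevalence, and score
with APRD/PRD. Runs are byte-for-byte reproducible from (config, seed).

All artifacts are plain CSV plus a JSON manifest.

## Acceptance

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance properties (oracle equivalences, closed-form limits,
parameter recovery, end-to-end truncation validation, bias directions,
determinism) are implemented in `tests/test_acceptance.py`. The reference
study's printed numbers derive from a confidential registry dataset, so the
report script validates the pipeline end to end and emits an empty target
map.

## Conventions

- Durations are completed years between diagnosis and the index date
  (anniversary floor); a diagnosis on the index date is not prevalent.
- `d`-year limited-duration prevalence counts completed durations `< d`.
- Age at prevalence = age at diagnosis + completed duration; model-based
  index ages follow the reconstruction convention (diagnosis age
  `a - t - 1`), one year older on the same person.
- Age groups: 5-year with 85+ (model scheme) or 0-29 / 5-year / 80+
  (empirical scheme).
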