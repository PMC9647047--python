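# pairsig

Rank-based gene-pair prognostic signatures for censored survival cohorts.

`pairsig` builds and evaluates prognostic signatures whose features are
within-sample gene-pair orderings: for an oriented pair *(A, B)* the feature
is the binary indicator `expr(A) > expr(B)`.  Because only orderings enter,
signatures transfer across platforms without normalization — any strictly
monotone per-sample transform of the expression values leaves every score
unchanged.

The full analysis pipeline is:

1. **Variability screen** — keep genes with median absolute deviation > 0.5
   across samples (raw MAD; the 1.4826 consistency constant is optional).
2. **Pair encoding** — enumerate all gene pairs once into a 0-or-1
   indicator matrix (ties score 0).
3. **Prevalence filter** — drop pairs scoring 1 in fewer than 20% or more
   than 80% of samples (inclusive bounds).
4. **Univariate Cox screen** — keep pairs with Wald p < 0.05.
5. **LASSO-Cox selection** — repeated cross-validated L1-penalized Cox
   (scikit-survival coxnet; penalty by cross-validated partial likelihood;
   stability threshold 50% across repetitions).
6. **Multivariate refit** — unpenalized Cox coefficients become the
   signature weights; `risk score = Σ βᵢ · indicatorᵢ`.
7. **Evaluation** — 1/2/3-year time-dependent ROC (Kaplan–Meier
   cumulative/dynamic estimator), Youden-index cutoff on the 3-year curve,
   high/low-risk Kaplan–Meier + log-rank, Cox models with clinical
   covariates, chi-square/Wilcoxon/Spearman associations, and TMB
   (mutations per megabase, 38 Mb exome).

A published 23-pair signature (28 genes) ships as the packaged fixture
`"table2"`.  A synthetic-cohort generator with planted pair effects
(Weibull proportional hazards, tuned exponential censoring, Table-1-like
clinical covariates) makes every stage testable offline.

## CLI

All commands read a single YAML config.  Exit codes: 0 success, 2 input
error, 3 a pipeline stage emptied its output.

```sh
pairsig simulate --config config.yaml --out cohort/   # synthetic cohort
pairsig build    --config config.yaml                 # screen → LASSO → refit
pairsig score    --signature table2 --expression expr.tsv --out scores.tsv
pairsig evaluate --config config.yaml --signature out/signature.tsv
pairsig all      --config config.yaml                 # simulate+build+evaluate
```

Example config:

```yaml
seed: 1
expression: cohort/expression.tsv     # genes × samples TSV
clinical: cohort/clinical.tsv         # sample_id, os_days, event, covariates
mutations: cohort/mutations.tsv       # optional, for TMB
out_dir: out
mad_threshold: 0.5
prevalence_low: 0.2
prevalence_high: 0.8
screen_alpha: 0.05
lasso_repetitions: 1000
lasso_folds: 10
roc_horizons: [365, 730, 1095]
cutoff_policy: train_transfer         # or per_cohort
simulate:                             # used by `pairsig simulate` / `all`
  n_samples: 500
  n_marker_genes: 90
  planted_pairs: [[MG0001, MG0002, 0.5]]
```

## Layout

```
src/pairsig/
  cohort.py      synthetic cohorts, monotone platform distortion, export/load
  pairs.py       MAD filter, pair enumeration, prevalence filter
  survival.py    Kaplan–Meier, log-rank, Breslow Cox (Newton), screen, LASSO
  signature.py   signature model, packaged fixture, risk scores, stratify
  evaluation.py  time-dependent ROC, Youden, clinical Cox, associations, TMB
  pipeline.py    build/evaluate orchestration, YAML config
  cli.py         click CLI
  data/table2_signature.tsv   packaged 23-pair signature
tests/           unit + property tests; test_acceptance.py mirrors the
                 acceptance criteria (fixture integrity, rank invariance,
                 brute-force oracles, null calibration, planted recovery,
                 equivalence identities)
scripts/acceptance.py
```
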