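# discopad

Distance-correlation-based estimation of the effective number of tests
(Meff) for single-step multiple-testing correction in metabolome-wide (and
other omics) association studies.

When M per-feature tests are correlated, the Bonferroni/Šidák pointwise
levels built from the raw count M are too conservative. `discopad` instead
estimates the effective number of tests from the eigenvalue spectrum of a
feature association matrix and supports three association measures —
Pearson, Spearman, and **distance correlation** (which detects both linear
and non-linear dependence) — together with:

- an exact O(n log n) univariate distance-covariance algorithm, verified
  against a direct double-centering implementation;
- nearest-positive-semidefinite repair (Frobenius-norm eigenvalue
  clipping) and eigenvalue flooring (default 1e-12) before eigen-analysis;
- five eigen-analysis Meff estimators: Nyholt, Li–Ji, Gao (PCs explaining
  ≥ 99.5% of total variation), Galwey, and Peluso (which may exceed M),
  plus the Bonferroni/Šidák baselines;
- Bonferroni-type (α/Meff) and Šidák-type (1−(1−α)^(1/Meff)) pointwise
  thresholds, with grouped estimation (per-group Meff summed across a
  feature partition);
- per-feature testing: covariate-adjusted linear-regression p-values and
  Welch's two-sample t-test, vectorized across features;
- a permutation gold standard: the ⌊αK⌋-th smallest of K minimum p-values
  under outcome shuffling estimates the gold pointwise level αf0, with
  Meff0 = α/αf0 and a Gaussian-binomial confidence interval;
- synthetic-data generators (MVN from a template, block-equicorrelated,
  nonlinearly dependent pairs, null outcomes, random partitions) and a
  simulation harness reporting median/MAD/RMSE against per-repetition
  gold standards.

## Library quick start

```python
from discopad import disco_pad, permutation_gold, nonlinear_pairs, null_outcome

X = nonlinear_pairs(n_pairs=25, n=100, seed=1)          # 50 features
est, thr = disco_pad(X, estimator="liji", alpha=0.05,
                     style="sidak-type", corr_method="distance")
print(est.value, thr.pwer)

y = null_outcome(100, "continuous", seed=2)
gold = permutation_gold(X, y, alpha=0.05, K=1000, seed=3)
print(gold.meff0, gold.ci)
```

## Command line

```sh
# Meff + adjusted pointwise threshold from a samples-by-features TSV
discopad meff --input abundances.tsv --corr distance --estimator liji \
    --alpha 0.05 --style sidak-type

# permutation gold standard (requires metadata with the outcome column)
discopad gold --input abundances.tsv --metadata meta.tsv --outcome fev1fvc \
    --covariates age,bmi,packyears --permutations 10000 --alpha 0.05 --seed 7

# pointwise threshold from a known Meff
discopad adjust --alpha 0.05 --meff 761 --style sidak-type

# synthetic data and simulation studies
discopad simulate-data --generator nonlinear --n 100 --m 50 --seed 1 --out-prefix sim
discopad simulate --config study.yaml --out-prefix study
```

Exit codes: 0 success, 1 usage error, 2 data error. Every stochastic
subcommand takes `--seed` and reruns reproduce outputs bit-for-bit.
Grouped estimation uses a two-column TSV (feature_id, group) via
`--groups`; features missing from the map are an error unless
`--allow-ungrouped` is given. Constant features abort matrix construction
unless `--drop-constant` is set.

A `simulate` YAML config looks like:

```yaml
generator: nonlinear        # identity | block | nonlinear | template
gen_params: {noise_sd: 0.1, form: square}
n: 100
M: 50
reps: 20
K: 1000
alpha: 0.05
estimators: [nyholt, liji, gao, galwey, peluso]
corr_methods: [pearson, distance]
groupings:
  random: {cardinalities: [25, 25]}
seed: 1
```

## Notes on conventions

- Association matrices store signed Pearson/Spearman entries and the
  distance correlation R ∈ [0, 1]; eigenvalues are handled descending.
- Nyholt uses the sample variance (M−1 denominator); Gao's cumulative
  threshold is inclusive (≥ 99.5%); Li–Ji snaps eigenvalues within 1e-9
  of an integer before the integer/fractional split.
- Peluso's reference eigenvalue defaults to the largest
  (`--peluso-lambda=max`; the only reading that can produce Meff > M);
  `min` preserves the ascending-index reading.
- Significance calls use p ≤ pwer (boundary inclusive). Reported Meff
  values are rounded only at the reporting layer.
- The permutation order statistic is ⌊αK⌋ (1-based): exact when αK is
  integral, conservative otherwise.
- MAD is unscaled by default (`median_mad(..., scale=1.4826)` for the
  normal-consistent convention).
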