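# Methods

## Normalization methods and chaining

All six methods operate column-wise with **population** moments (divide by
n): the formulas are stated directly in terms of the column mean and
standard deviation, and nothing in the method requires an unbiased
variance estimate. PSN divides by the square root of the standard
deviation (classic Pareto scaling); dividing by the square root of the
variance would make PSN identical to ZSN and collapse two methods that
behave differently in practice.

A chain applies its methods sequentially, each step recomputing column
statistics on the previous step's output. Chains are enumerated as all
non-empty subsets of the method list, applied in input-list order —
$2^n-1$ chains for $n$ methods; orderings beyond the input order are not
explored (brute-force subset comparison, not permutation search).

Degenerate columns are a designed-for case, not an error: zero-variance,
zero-range or zero-MAD columns map to all-zero columns with a warning
naming the column. This matters because chains *create* constant columns
— z-scoring makes every column mean-zero, so a subsequent VSS step (whose
scale factor is the coefficient of variation $\mu/\sigma$) annihilates the
entire matrix. For this identity to hold exactly in floating point, VSS
snaps a mean smaller than $10^{-12}\sigma$ to zero; otherwise rounding
residue of order $10^{-16}$ would survive and, worse, acquire arbitrary
ranks downstream.

Rank transformation assigns ascending ranks $1..n$ per column with
average ranks for ties (keeping the per-column rank sum at $n(n+1)/2$).
Ties-averaging is the standard choice and makes the transform idempotent
up to relabeling.

By default all statistics (normalization, selector standardization) are
computed on the matrix being transformed — the whole-dataset preprocessing
the pipeline is defined with. `ChainNormalizer(refit=False)` provides a
leakage-free alternative that freezes each step's statistics on the
training data; it is off by default because the reference procedure
transforms the full table before model training, and the evaluation
compares engineered representations, not deployment pipelines.

## Dataset variants

Six variants per chain: `raw`, `pre_rank`, `post_rank`, and the three
horizontal merges `raw_and_pre`, `raw_and_post`, `pre_and_post`. Both
paths start from pristine inputs — the raw matrix (post-rank path) or the
rank-transformed raw matrix (pre-rank path); chains never accumulate
state across combinations. Merged feature IDs are prefixed `raw::`,
`pre::`, `post::` so provenance survives selection and slicing.

## Feature selection

Importance is the absolute coefficient of an L2-penalized logistic
regression (`C = 1/reg_strength`, default `reg_strength = 1`) fitted on
per-column standardized features; features scoring strictly above the
threshold (default 0.1) are kept in original order. The strict inequality
and the `>=` alternative are both exposed. If nothing survives, the
selector fails loudly naming the maximum observed score, unless a
`fallback_topk` is configured (the grid runner uses `fallback_topk=16` so
a weak cell degrades instead of erroring). An L1 penalty is available as
an option for comparison.

## Classifier and evaluation protocol

The network is input → 512 ReLU → 256 ReLU → 1 sigmoid, Adam with
learning rate 0.001, binary cross-entropy — scikit-learn's
`MLPClassifier` realizes exactly this in its binary mode and is used as
the backend. Trainable parameters number
$(d+1)\cdot512 + 513\cdot256 + 257$, i.e. 297,985 for $d=324$. Loss,
epochs (default 100), batch size (default 16) and initialization follow
the backend's conventions and are all configurable; the input width is
always inferred from the post-selection feature count. Class weighting is
off by default (the typical cohort imbalance, 33 cases in 112 samples, is
left as-is); a balanced mode exists.

Evaluation is stratified k-fold CV (default k=5, optional repeats):
out-of-fold probabilities, per-fold AUC, pooled confusion matrix at
probability cut-off 0.5 (configurable). The positive class is the disease
(CRC) label; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
FPR = 1 − specificity, and rates with empty denominators return an
explicit `None`, never a silent NaN. AUC is computed by
`sklearn.metrics.roc_auc_score`; the test suite verifies it against a
brute-force pair-counting oracle. Fold splits depend only on labels and
the split seed; weight initialization uses its own logged seed, and with
both fixed the whole evaluation is bit-reproducible (single-threaded CPU
backend with deterministic ops).

A logistic-regression baseline under the identical protocol is provided
(`model.logistic_baseline`) as a sanity reference for linearly separable
inputs.

## Distribution analysis and significance

`distribution_summary` reports kurtosis, skewness, std, max, min, mean
and the 25th/50th/75th percentiles over the pooled matrix entries
(per-column averaging is available). Kurtosis is the **excess** convention
(normal → 0), switchable. `auc_distribution_regression` fits OLS of AUC
on chosen attributes (default kurtosis + skewness) via statsmodels,
reporting coefficients with t- and p-values, residual SE, R², adjusted
R², the F test, and the correlation matrix among AUC, time and all nine
attributes.

`compare_methods` defaults to the paired Wilcoxon signed-rank test on
fold-level AUCs (comparisons share folds); the unpaired rank-sum
(Mann-Whitney) form is selected with `paired=False`. Both are two-sided
by default, exact where sample size and tie structure permit, otherwise
the tie-corrected normal approximation. All-zero paired differences
return a flagged degenerate result with p = 1.

## Synthetic cohorts

The generator emulates the statistical structure the method targets:

- base taxon proportions: log-normal, $\sigma = 2$ (heavy tail);
- per-sample composition: Dirichlet around the class's expected
  proportions with concentration 50 (overdispersion);
- counts: multinomial with log-normal library size (mean 50,000, CV 0.3);
- zero inflation to an overall target sparsity of 0.6;
- closure to relative abundances (rows sum to 1 within 1e-9).

Cases multiply the expected proportions of `n_informative` (default 10)
planted taxa by $e^{\mathrm{lfc}}$ (default log-fold-change 2) before
renormalization. Informative taxa are drawn from the upper half of base
abundance: planting an effect on a taxon too rare to ever be observed
produces no signal at any effect size, and real differentially abundant
taxa in disease cohorts are by definition detectable. Presets:
`dataset1-like` (112 × 324, 33 cases) and `dataset2-like` (884 × 2031,
368 cases / 516 controls).

What the simulator does **not** emulate: taxon-taxon correlation
structure beyond the compositional constraint, batch/country effects,
read-level noise, or taxonomy. Passing tests therefore demonstrate that
the pipeline behaves as designed under the assumed generative model —
compositional, sparse, heavy-tailed data with monotone measurement
warping — not that any particular AUC will be attained on a real cohort.

`monotone_distort` supplies the warping harness: random strictly
increasing per-column maps (power, log1p, affine families) that preserve
ranks exactly, used to verify rank-path invariance and to create the
regimes where rank-based features should win.

## Problem sizes used in the shipped checks

The test suite and acceptance script run deliberately scaled-down
configurations chosen to exercise every code path at desk scale: 5–10
simulated cohorts per claim, 112 × 324 tables, 30 training epochs for
pipeline comparisons and 15 for null controls, 5-fold CV, and the
`vss,psn` chain (the strongest two-method chain in the reference grid) as
the representative chain. The full 15-chain × 6-variant × FS grid runs
through `chainrank experiment` when more compute is available.

## Known limitations

- Whole-dataset normalization and selection (the default) leak
  information across CV folds by construction; conclusions are about
  representation quality under the stated protocol. The `refit=False`
  normalizer mode exists for leakage-free workflows but is not the
  evaluated configuration.
- Importance selection with a fixed absolute threshold (0.1) is sensitive
  to the regularization strength; the two knobs are exposed together.
- The network backend trains single-threaded on CPU; very wide merged
  tables (shotgun-scale presets with all chains) are compute-heavy —
  the grid runner records per-cell wall time but draws no conclusions
  from it.
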