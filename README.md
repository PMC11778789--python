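# chainrank

Feature engineering for microbiome-based disease classification: chained
normalization, dual-path rank transformation, feature extension, and
L2-importance feature selection, feeding a dense neural-network classifier
evaluated by cross-validated AUC.

## The problem

Gut-microbiome abundance tables (OTU/ASV or shotgun taxonomic profiles) are
hostile inputs for machine learning: they are compositional (each sample's
abundances sum to 1, so only relative information exists), sparse (most
entries are zero), heavy-tailed (a few taxa dominate), and measured through
platform-dependent pipelines that warp the scale of each feature. A
classifier trained directly on such a table — for example a colorectal
cancer (CRC) vs. healthy classifier — inherits all of these pathologies.

`chainrank` implements a hybrid feature-engineering method that attacks
them jointly. For each feature column $a_{\cdot j}$ with population mean
$\mu_j$ and population standard deviation $\sigma_j$ it provides four core
normalization methods,

| method | formula |
|---|---|
| ZSN (z-score) | $(a_{ij}-\mu_j)/\sigma_j$ |
| PSN (Pareto scaling) | $(a_{ij}-\mu_j)/\sqrt{\sigma_j}$ |
| VSS (variable stability scaling) | $\frac{a_{ij}-\mu_j}{\sigma_j}\cdot\frac{\mu_j}{\sigma_j}$ |
| MMN (min-max) | $(a_{ij}-\min_j)/(\max_j-\min_j)$ |

plus two optional extras (sigmoid squashing of the z-score, and median/MAD
scaling). Because no single method suits every data distribution, methods
are **chained**: each method's output feeds the next, and all $2^n-1$
ordered subsets of the method list can be enumerated and compared.

Two parallel paths then derive new feature sets:

- **Post-Rank**: chain-normalize the raw table, then replace every column
  by its ascending ranks (ties averaged);
- **Pre-Rank**: rank-transform first, then chain-normalize the ranks.

The rank step makes the features invariant to any strictly increasing
per-feature distortion of the measurements. The paths are merged
horizontally with or without the raw features (**feature extension**, six
dataset variants in total), and the merged columns are filtered by
**L2-importance selection**: the absolute coefficients of an L2-penalized
logistic regression on standardized features, keeping features scoring
above 0.1. The selected features train a dense network (input → 512 ReLU
→ 256 ReLU → 1 sigmoid, Adam, learning rate 0.001) evaluated by
stratified 5-fold cross-validated AUC, with Wilcoxon tests comparing
fold-level AUCs between variants and an OLS analysis relating AUC to the
engineered data's distribution shape (kurtosis, skewness, …).

Because real cohort data is not redistributable, the package ships a
Dirichlet-multinomial cohort simulator (log-normal base abundances,
overdispersion, zero inflation, planted differentially abundant taxa) with
presets shaped like a 112-sample / 324-feature amplicon cohort
(`dataset1-like`) and an 884-sample / 2031-feature shotgun compilation
(`dataset2-like`), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from chainrank import (preset, simulate, monotone_distort, build_variant,
                       RidgeImportanceSelector, apply_selection, train_eval_cv)
from chainrank.model import DNNConfig, CVProtocol

cohort = simulate(preset("dataset1-like", seed=1))

# emulate platform warping: per-taxon monotone distortion + 5% noise
distorted = monotone_distort(cohort.table, "affine", seed=1)
rng = np.random.default_rng(1)
scale = 0.05 * distorted.values.std(axis=0, keepdims=True) + 1e-12
table = distorted.with_values(
    distorted.values + rng.normal(scale=scale, size=distorted.values.shape))

cfg, cv = DNNConfig(epochs=30, seed=0), CVProtocol(k=5, seed=0)
raw = train_eval_cv(build_variant(table, None, "raw"), cohort.labels, cfg, cv)

ds = build_variant(table, ["vss", "psn"], "pre_and_post")
sel = RidgeImportanceSelector(threshold=0.1, fallback_topk=16, random_state=0)
sel.fit(ds.matrix.values, cohort.labels)
ds_sel = apply_selection(ds, sel.selection_result())
eng = train_eval_cv(ds_sel, cohort.labels, cfg, cv)
```

Output on this cohort:

```
table: (112, 324) | cases: 33
raw features:        mean CV AUC = 0.732
pre_and_post variant: 648 features
after selection:      46 features
engineered + FS:     mean CV AUC = 1.000
sensitivity = 1.000, specificity = 1.000
```

The raw-feature network is crippled by the warped scales (AUC 0.732); the
`pre_and_post` variant of the `vss,psn` chain — 648 rank-based features
cut to 46 by importance selection — restores clean separation. The same
comparison is what the grid runner (`chainrank experiment`) executes over
all chains, variants, and selection settings.

The same flows are available from the shell:

```bash
chainrank simulate --preset dataset1-like --seed 1 --out cohort.tsv
chainrank engineer --input cohort.tsv --chain vss,psn --variant pre_and_post --output eng.tsv
chainrank select   --input eng.tsv --threshold 0.1 --scores-out scores.tsv
chainrank experiment --preset dataset1-like --chains "vss,psn" --fs both \
    --epochs 30 --seed 1 --out results.json
chainrank report --results results.json --outdir report/
```

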