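# smbacsfs

Sparse self-representation feature selection for expression data, with a
class-specific ensemble extension.

The core selector expresses every feature (column) of a data matrix as a
sparse **affine** combination of the other features by solving

```
minimize_C  (1/2) ||X - XC||_F^2 + lam * sum_i ||c^i||_q    s.t.  1^T C = 1^T
```

with ADMM (`q` in {2, inf}; the row-sparsity penalty deselects features,
the unit-column-sum constraint makes selection translation invariant).
Features are ranked by the norms of their coefficient rows.

The class-specific pipeline splits the training samples by class,
balances them with SMOTE, runs the selector inside each class to get one
ranking per class, and trains one multi-class classifier per class on
that class's top-j features.  Predictions are aggregated by a cascaded
majority rule: a unique "self-vote" (a member predicting its own class)
wins outright, multiple self-votes are settled by total vote counts,
no self-vote falls back to a plain plurality, and residual ties are
drawn with a seeded RNG.

Evaluation runs K-fold cross-validation over a grid of feature counts,
reporting accuracy, macro precision/recall/F1 and one-vs-rest macro AUC
per fold, plus Friedman/Nemenyi rank statistics for comparing methods
across datasets.  Synthetic generators provide self-expressive and
multi-class fixtures so everything is testable without external data.

## CLI

```sh
# generate a synthetic multi-class dataset (with a ground-truth sidecar)
smbacsfs simulate --kind multiclass --classes 6 --n-features 500 \
    --informative 20 --effect-size 2.0 --seed 1 \
    --out-matrix expr.tsv --out-labels labels.tsv --out-truth truth.json

# whole-matrix feature ranking
smbacsfs select --matrix expr.tsv --out ranking.tsv --alpha 2.0

# cross-validated class-specific pipeline (Average Classification Metrics)
smbacsfs csfs --matrix expr.tsv --labels labels.tsv \
    --m 20 --k-folds 5 --classifier svm --seed 1 \
    --out-json acm.json --out-tsv acm.tsv

# Friedman + Nemenyi over a datasets x methods score table
smbacsfs rank-test --scores scores.tsv --alpha 0.05 --out friedman.json
```

Flags override config-file values (`--config cfg.yaml`, flat keys
mirroring the flags), which override defaults.  `--paper-faithful`
standardizes/balances/shuffles the whole dataset *before* fold
splitting (reproducing a leaky pipeline order); the default fits the
z-score and SMOTE inside each training fold only.  Matrices are
tab-separated with header and row ids, samples as rows by default
(`--orientation features_by_samples` to transpose on load); labels are
a two-column `sample_id<TAB>label` file.

## Library

```python
from smbacsfs import (FeatureMatrix, SMBAParams, solve_smba, rank_features,
                      CSFSConfig, run_csfs_cv)

result = solve_smba(X, SMBAParams(alpha=2.0))   # lam = lambda_reference(X)/alpha
ranking = rank_features(result)
report = run_csfs_cv(dataset, CSFSConfig(m=20, K=5, feature_grid=(10, 20)))
```

`SMBAParams(rho=None)` matches the ADMM penalty to the regularization
scale, which converges much faster on standardized high-dimensional
data than the literal default `rho=1.0`.

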