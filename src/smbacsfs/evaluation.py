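"""Cross-validated evaluation over feature counts, plus rank statistics.

The CV loop standardizes and class-balances inside each training fold
(default, leak-free) or on the whole dataset up front (``faithful``
mode, matching the printed pipeline order), runs the per-class selector
once per fold, then sweeps the number of features ``j`` reusing ranking
prefixes.  Cross-method comparison uses the Friedman rank test and the
Nemenyi critical difference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import label_binarize

from smbacsfs.core_smba import (
    FeatureMatrix,
    SMBAParams,
    ValidationError,
    rank_features,
    solve_smba,
)
from smbacsfs.csfs_ensemble import (
    LabeledDataset,
    build_ensemble,
    make_classifier,
    predict,
    select_class_specific,
    smote_balance,
    vote_share_matrix,
)

logger = logging.getLogger(__name__)

# studentized-range constants q_alpha / sqrt(2) for the Nemenyi test,
# k = 2..20 (Demsar 2006, two-tailed)
_NEMENYI_Q = {
    0.05: [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164,
           3.219, 3.268, 3.313, 3.354, 3.391, 3.426, 3.458, 3.489, 3.517, 3.544],
    0.10: [1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920,
           2.978, 3.030, 3.077, 3.120, 3.159, 3.196, 3.230, 3.261, 3.291, 3.319],
}


@dataclass(frozen=True)
class CSFSConfig:
    """Configuration of the cross-validated feature-count sweep."""

    m: int = 80
    K: int = 5
    classifier_spec: object = "svm"
    # pipeline default: rho matched to the penalty scale (fast convergence
    # on standardized high-dimensional folds), slightly looser tolerance
    smba: SMBAParams = field(
        default_factory=lambda: SMBAParams(rho=None, delta=1e-4, max_iter=1000)
    )
    seed: int = 0
    faithful: bool = False
    feature_grid: tuple[int, ...] = ()
    stratified: bool = True
    smote_k: int = 5
    average: str = "macro"

    def __post_init__(self):
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.K < 2:
            raise ValidationError("K must be >= 2")
        grid = tuple(self.feature_grid) or tuple(range(1, self.m + 1))
        if any(j < 1 or j > self.m for j in grid):
            raise ValidationError("feature_grid values must lie in [1, m]")
        if self.average not in ("macro", "micro"):
            raise ValidationError("average must be 'macro' or 'micro'")
        object.__setattr__(self, "feature_grid", grid)


@dataclass(frozen=True)
class MetricRecord:
    fold: int
    j: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float

    def __post_init__(self):
        for name in ("accuracy", "precision", "recall", "f1", "auc"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0 + 1e-12):
                raise ValidationError(f"{name}={v} outside [0, 1]")


_METRICS = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class ACMReport:
    """Per-feature-count, per-fold metrics and their cross-fold summary."""

    records: list[MetricRecord]
    config: dict
    summary: dict[int, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.summary:
            self.summary = self._summarize()

    def _summarize(self) -> dict[int, dict[str, tuple[float, float]]]:
        out: dict[int, dict[str, tuple[float, float]]] = {}
        by_j: dict[int, list[MetricRecord]] = {}
        for r in self.records:
            by_j.setdefault(r.j, []).append(r)
        for j, recs in sorted(by_j.items()):
            out[j] = {}
            for name in _METRICS:
                vals = np.asarray([getattr(r, name) for r in recs], dtype=float)
                out[j][name] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out

    def mean(self, metric: str, j: int) -> float:
        return self.summary[j][metric][0]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "summary": {
                str(j): {m: list(v) for m, v in row.items()}
                for j, row in self.summary.items()
            },
            "records": [r.__dict__ for r in self.records],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_tidy(self) -> pd.DataFrame:
        rows = [
            {"fold": r.fold, "j": r.j, "metric": name, "value": getattr(r, name)}
            for r in self.records
            for name in _METRICS
        ]
        return pd.DataFrame(rows, columns=["fold", "j", "metric", "value"])

    def to_tsv(self, path) -> None:
        self.to_tidy().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RankTable:
    """Datasets (rows) x methods (columns) score matrix for rank tests."""

    scores: np.ndarray
    methods: tuple[str, ...]
    higher_is_better: bool = True

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2:
            raise ValidationError("scores must be 2-D")
        if not np.isfinite(scores).all():
            raise ValidationError("scores contain missing or non-finite entries")
        if len(self.methods) != scores.shape[1]:
            raise ValidationError("one method name per column is required")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "methods", tuple(self.methods))


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    average_ranks: np.ndarray


def zscore_fit_apply(
    train: FeatureMatrix, others: Sequence[FeatureMatrix] = ()
) -> tuple[FeatureMatrix, list[FeatureMatrix], np.ndarray, np.ndarray]:
    """Standardize per feature with train statistics (population sd).

    Zero-variance features have their sd clamped to 1, which maps the
    train column to exactly 0.  The same affine transform is applied to
    every matrix in ``others``.
    """
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0)  # population convention (divisor m)
    sd = np.where(sd == 0, 1.0, sd)

    def apply(mat: FeatureMatrix) -> FeatureMatrix:
        return FeatureMatrix(
            values=(mat.values - mean) / sd,
            feature_ids=mat.feature_ids,
            sample_ids=mat.sample_ids,
        )

    return apply(train), [apply(o) for o in others], mean, sd


def kfold_split(
    labels, K: int, seed: int = 0, stratified: bool = True
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled (optionally stratified) K-fold index partition."""
    labels = np.asarray(labels)
    if K > labels.size:
        raise ValidationError(f"K={K} exceeds the {labels.size} samples")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if K > counts.min():
            raise ValidationError(
                f"stratified K={K} exceeds the smallest class ({counts.min()} samples)"
            )
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(labels.size), labels)]


def compute_metrics(
    y_true, y_pred, score_matrix, classes, average: str = "macro"
) -> dict[str, float]:
    """Accuracy, averaged P/R/F1 and one-vs-rest AUC for one fold.

    ``score_matrix`` columns must follow ``classes`` order.  AUC is
    averaged over the classes that have both positives and negatives in
    ``y_true``; a single-class truth vector is an error.
    """
    y_true = np.asarray([str(y) for y in y_true])
    y_pred = np.asarray([str(y) for y in y_pred])
    classes = [str(c) for c in classes]
    if y_true.size != y_pred.size:
        raise ValidationError("y_true and y_pred length mismatch")
    if np.unique(y_true).size < 2:
        raise ValidationError("AUC undefined: y_true contains a single class")
    score_matrix = np.asarray(score_matrix, dtype=float)
    if score_matrix.shape != (y_true.size, len(classes)):
        raise ValidationError("score_matrix must be n_samples x n_classes")

    acc = accuracy_score(y_true, y_pred)
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=average, zero_division=0
    )
    onehot = label_binarize(y_true, classes=classes)
    if len(classes) == 2:
        onehot = np.column_stack([1 - onehot[:, 0], onehot[:, 0]])
    aucs = [
        roc_auc_score(onehot[:, k], score_matrix[:, k])
        for k in range(len(classes))
        if 0 < onehot[:, k].sum() < y_true.size
    ]
    return {
        "accuracy": float(acc),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f1),
        "auc": float(np.mean(aucs)),
    }


def _prepare_folds(dataset: LabeledDataset, config: CSFSConfig):
    """Yield (train, test) LabeledDatasets, preprocessing per mode."""
    if config.faithful:
        logger.info(
            "faithful mode: standardization, SMOTE and shuffling are applied "
            "to the FULL dataset before fold splitting (information leaks "
            "from test to train by construction)"
        )
        std, _, _, _ = zscore_fit_apply(dataset.matrix)
        full = smote_balance(
            LabeledDataset(std, dataset.labels, dataset.classes),
            k_neighbors=config.smote_k,
            seed=config.seed,
        )
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(full.matrix.n_samples)
        full = full.subset(perm)
        for tr, te in kfold_split(full.labels, config.K, config.seed, config.stratified):
            yield full.subset(tr), full.subset(te)
    else:
        logger.info(
            "leak-free mode: z-score and SMOTE are fit inside each training fold"
        )
        for tr, te in kfold_split(
            dataset.labels, config.K, config.seed, config.stratified
        ):
            train, test = dataset.subset(tr), dataset.subset(te)
            std_train, (std_test,), _, _ = zscore_fit_apply(train.matrix, [test.matrix])
            train = smote_balance(
                LabeledDataset(std_train, train.labels, dataset.classes),
                k_neighbors=config.smote_k,
                seed=config.seed,
            )
            yield train, LabeledDataset(std_test, test.labels, dataset.classes)


def run_csfs_cv(dataset: LabeledDataset, config: CSFSConfig) -> ACMReport:
    """Class-specific selection + per-class ensemble, across folds and j."""
    records: list[MetricRecord] = []
    for fold, (train, test) in enumerate(_prepare_folds(dataset, config)):
        fsets = select_class_specific(train, config.smba, config.m)
        for j in config.feature_grid:
            ensemble = build_ensemble(
                train, fsets, j, config.classifier_spec,
                seed=config.seed + 1000 * fold + j,
            )
            outcomes = predict(ensemble, test.matrix)
            y_pred = [o.label for o in outcomes]
            scores = vote_share_matrix(outcomes, dataset.classes)
            metrics = compute_metrics(
                test.labels, y_pred, scores, dataset.classes, config.average
            )
            records.append(MetricRecord(fold=fold, j=j, **metrics))
    return ACMReport(records=records, config=_config_dict(config, "csfs"))


def run_smba_cv(dataset: LabeledDataset, config: CSFSConfig) -> ACMReport:
    """Single whole-training-fold selection + one classifier (no ensemble)."""
    records: list[MetricRecord] = []
    for fold, (train, test) in enumerate(_prepare_folds(dataset, config)):
        coeff = solve_smba(train.matrix, config.smba)
        ranking = rank_features(coeff, config.smba.q)
        y_train = np.asarray(train.labels)
        for j in config.feature_grid:
            cols = ranking.top(j)
            clf = make_classifier(config.classifier_spec)
            clf.fit(train.matrix.values[:, cols], y_train)
            y_pred = clf.predict(test.matrix.values[:, cols])
            if hasattr(clf, "decision_function"):
                raw = clf.decision_function(test.matrix.values[:, cols])
            elif hasattr(clf, "predict_proba"):
                raw = clf.predict_proba(test.matrix.values[:, cols])
            else:
                raw = label_binarize(
                    y_pred, classes=[str(c) for c in clf.classes_]
                ).astype(float)
                if len(clf.classes_) == 2:
                    raw = np.column_stack([1 - raw[:, 0], raw[:, 0]])
            scores = _align_scores(raw, clf.classes_, dataset.classes)
            metrics = compute_metrics(
                test.labels, y_pred, scores, dataset.classes, config.average
            )
            records.append(MetricRecord(fold=fold, j=j, **metrics))
    return ACMReport(records=records, config=_config_dict(config, "smba"))


def _align_scores(raw: np.ndarray, clf_classes, classes) -> np.ndarray:
    """Map classifier score columns onto the global class order."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:  # binary decision_function
        raw = np.column_stack([-raw, raw])
    out = np.zeros((raw.shape[0], len(classes)))
    pos = {str(c): k for k, c in enumerate(clf_classes)}
    for k, c in enumerate(classes):
        if str(c) in pos:
            out[:, k] = raw[:, pos[str(c)]]
        else:
            out[:, k] = raw.min() - 1.0  # class unseen in training fold
    return out


def _config_dict(config: CSFSConfig, pipeline: str) -> dict:
    return {
        "pipeline": pipeline,
        "m": config.m,
        "K": config.K,
        "classifier_spec": str(config.classifier_spec),
        "seed": config.seed,
        "faithful": config.faithful,
        "feature_grid": list(config.feature_grid),
        "stratified": config.stratified,
        "smote_k": config.smote_k,
        "average": config.average,
        "smba": {
            "lam": config.smba.lam,
            "alpha": config.smba.alpha,
            "rho": config.smba.rho,
            "delta": config.smba.delta,
            "eta": config.smba.eta,
            "q": "inf" if config.smba.q == np.inf else config.smba.q,
            "max_iter": config.smba.max_iter,
        },
    }


def friedman_statistic(table: RankTable) -> FriedmanResult:
    """Friedman chi-square over per-row midranks (rank 1 = best)."""
    scores = table.scores
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 datasets and 2 methods")
    oriented = -scores if table.higher_is_better else scores
    ranks = np.vstack([stats.rankdata(row, method="average") for row in oriented])
    avg = ranks.mean(axis=0)
    statistic = 12.0 * n / (k * (k + 1)) * (np.sum(avg**2) - k * (k + 1) ** 2 / 4.0)
    statistic = max(statistic, 0.0)
    p_value = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    return FriedmanResult(
        statistic=float(statistic), p_value=p_value, average_ranks=avg
    )


def nemenyi_critical_difference(k: int, N: int, alpha: float = 0.05) -> float:
    """Critical difference of average ranks: CD = q_a * sqrt(k(k+1)/(6N))."""
    if k < 2 or N < 1:
        raise ValidationError("need k >= 2 methods and N >= 1 datasets")
    if alpha not in _NEMENYI_Q:
        raise ValidationError(f"alpha must be one of {sorted(_NEMENYI_Q)}")
    q_table = _NEMENYI_Q[alpha]
    if k - 2 >= len(q_table):
        raise ValidationError(f"tabulated constants cover k <= {len(q_table) + 1}")
    return q_table[k - 2] * np.sqrt(k * (k + 1) / (6.0 * N))
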