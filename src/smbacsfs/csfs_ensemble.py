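"""Class-specific feature selection and the per-class voting ensemble.

Pipeline: split the training samples by class, balance the classes with
SMOTE, run the sparse self-representation selector inside each class to
get one feature ranking per class, then train one multi-class classifier
per class on that class's top-j features.  A cascaded majority rule
(self-votes first, plain plurality as fallback, seeded random draw on
residual ties) aggregates the member predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from smbacsfs.core_smba import (
    EmptySelectionError,
    FeatureMatrix,
    FeatureRanking,
    SMBAParams,
    ValidationError,
    rank_features,
    solve_smba,
)

#: named classifier specs (the linear-kernel SVM is the primary one)
_CLASSIFIERS = {
    "svm": lambda: SVC(kernel="linear", C=1.0),
    "svm_linear": lambda: SVC(kernel="linear", C=1.0),
    "knn": lambda: KNeighborsClassifier(n_neighbors=5),
    "naive_bayes": lambda: GaussianNB(),
    "nb": lambda: GaussianNB(),
    "tree": lambda: DecisionTreeClassifier(random_state=0),
    "decision_tree": lambda: DecisionTreeClassifier(random_state=0),
}


def make_classifier(spec) -> BaseEstimator:
    """Instantiate a fresh classifier from a name or estimator prototype."""
    if isinstance(spec, str):
        try:
            return _CLASSIFIERS[spec]()
        except KeyError:
            raise ValidationError(
                f"unknown classifier {spec!r}; choose from {sorted(_CLASSIFIERS)}"
            ) from None
    if isinstance(spec, BaseEstimator):
        return clone(spec)
    raise ValidationError(f"classifier_spec must be a name or estimator, got {type(spec)}")


@dataclass(frozen=True)
class LabeledDataset:
    """Expression matrix plus a categorical label per sample."""

    matrix: FeatureMatrix
    labels: tuple[str, ...]
    classes: tuple[str, ...] = ()

    def __post_init__(self):
        labels = tuple(str(y) for y in self.labels)
        if len(labels) != self.matrix.n_samples:
            raise ValidationError(
                f"{len(labels)} labels for {self.matrix.n_samples} samples"
            )
        # class order is lexicographic unless supplied explicitly
        classes = tuple(self.classes) or tuple(sorted(set(labels)))
        if set(labels) - set(classes):
            raise ValidationError("labels contain classes missing from the class list")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "classes", classes)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for y in self.labels:
            counts[y] += 1
        return counts

    def subset(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            matrix=self.matrix.subset_samples(idx),
            labels=tuple(self.labels[i] for i in idx),
            classes=self.classes,
        )


@dataclass(frozen=True)
class ClassSubset:
    class_label: str
    matrix: FeatureMatrix


@dataclass(frozen=True)
class ClassFeatureSets:
    """One truncated feature ranking per class, shared index space."""

    rankings: dict[str, FeatureRanking]
    classes: tuple[str, ...]
    m_max: int

    def __post_init__(self):
        missing = set(self.classes) - set(self.rankings)
        if missing:
            raise ValidationError(f"missing rankings for classes {sorted(missing)}")

    def top(self, class_label: str, j: int) -> np.ndarray:
        ranking = self.rankings[class_label]
        if j > len(ranking):
            raise ValidationError(
                f"j={j} exceeds ranking length {len(ranking)} for class {class_label!r}"
            )
        return ranking.top(j)


@dataclass
class EnsembleModel:
    """One trained multi-class classifier per class, each on its own features."""

    members: list[tuple[str, np.ndarray, BaseEstimator]]
    classifier_spec: object
    j: int
    classes: tuple[str, ...]
    feature_ids: tuple[str, ...]
    rng: np.random.Generator


@dataclass(frozen=True)
class PredictionOutcome:
    label: str
    rule_path: str
    votes: dict[str, int]


def separate_by_class(dataset: LabeledDataset) -> list[ClassSubset]:
    """Partition samples into per-class submatrices, class order."""
    labels = np.asarray(dataset.labels)
    out = []
    for c in dataset.classes:
        idx = np.nonzero(labels == c)[0]
        out.append(ClassSubset(class_label=c, matrix=dataset.matrix.subset_samples(idx)))
    return out


def smote_balance(
    dataset: LabeledDataset, k_neighbors: int = 5, seed: int = 0
) -> LabeledDataset:
    """Oversample every minority class up to the majority count.

    Each synthetic sample is ``x + u * (x' - x)`` with ``u ~ U(0, 1)``,
    ``x`` a real minority sample and ``x'`` one of its ``k`` nearest
    same-class neighbors (Euclidean); ``k`` is capped at class size - 1.
    Original samples are preserved verbatim and an already balanced
    dataset is returned unchanged.
    """
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be a positive integer")
    counts = dataset.class_counts()
    majority = max(counts.values())
    if all(v == majority for v in counts.values()):
        return dataset

    rng = np.random.default_rng(seed)
    labels = np.asarray(dataset.labels)
    values = dataset.matrix.values
    new_rows, new_labels, new_ids = [], [], []
    for c in dataset.classes:
        deficit = majority - counts[c]
        if deficit == 0:
            continue
        if counts[c] < 2:
            raise ValidationError(
                f"class {c!r} has a single sample; cannot synthesize neighbors"
            )
        idx = np.nonzero(labels == c)[0]
        pts = values[idx]
        k = min(k_neighbors, counts[c] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        neigh = nn.kneighbors(pts, return_distance=False)[:, 1:]  # drop self
        for s in range(deficit):
            i = int(rng.integers(counts[c]))
            nb = int(neigh[i, int(rng.integers(k))])
            u = rng.uniform()
            new_rows.append(pts[i] + u * (pts[nb] - pts[i]))
            new_labels.append(c)
            new_ids.append(f"syn_{c}_{s}")

    matrix = FeatureMatrix(
        values=np.vstack([values, np.asarray(new_rows)]),
        feature_ids=dataset.matrix.feature_ids,
        sample_ids=dataset.matrix.sample_ids + tuple(new_ids),
    )
    return LabeledDataset(
        matrix=matrix, labels=dataset.labels + tuple(new_labels), classes=dataset.classes
    )


def _truncate(ranking: FeatureRanking, m: int) -> FeatureRanking:
    return FeatureRanking(
        order=ranking.order[:m],
        scores=ranking.scores[:m],
        feature_ids=ranking.feature_ids[:m],
    )


def select_class_specific(
    train: LabeledDataset, params: SMBAParams, m: int
) -> ClassFeatureSets:
    """Run the sparse selector inside each class and keep its top-m features."""
    if m < 1 or m > train.matrix.n_features:
        raise ValidationError(f"m must lie in [1, {train.matrix.n_features}]")
    rankings: dict[str, FeatureRanking] = {}
    for subset in separate_by_class(train):
        try:
            coeff = solve_smba(subset.matrix, params)
        except EmptySelectionError as err:  # pragma: no cover - defensive
            raise EmptySelectionError(f"class {subset.class_label!r}: {err}") from err
        rankings[subset.class_label] = _truncate(rank_features(coeff, params.q), m)
    return ClassFeatureSets(rankings=rankings, classes=train.classes, m_max=m)


def build_ensemble(
    train: LabeledDataset,
    fsets: ClassFeatureSets,
    j: int,
    classifier_spec="svm",
    seed: int = 0,
) -> EnsembleModel:
    """Train one member per class on all samples, restricted to that
    class's top-j features."""
    if train.n_classes < 2:
        raise ValidationError("an ensemble needs at least 2 classes")
    if j < 1:
        raise ValidationError("j must be a positive integer")
    y = np.asarray(train.labels)
    members = []
    for c in train.classes:
        cols = fsets.top(c, j)
        clf = make_classifier(classifier_spec)
        try:
            clf.fit(train.matrix.values[:, cols], y)
        except Exception as err:
            raise RuntimeError(f"training member for class {c!r} failed: {err}") from err
        members.append((c, np.asarray(cols, dtype=int), clf))
    return EnsembleModel(
        members=members,
        classifier_spec=classifier_spec,
        j=j,
        classes=train.classes,
        feature_ids=train.matrix.feature_ids,
        rng=np.random.default_rng(seed),
    )


def decide_majority(
    predictions, classes, rng: np.random.Generator
) -> PredictionOutcome:
    """Cascaded decision rule over the member predictions.

    Members whose prediction equals their own class are *self-votes*.
    A unique self-vote wins outright; several self-votes are settled by
    total vote counts restricted to the self-voted classes; no self-vote
    falls back to a plain plurality.  Residual ties are drawn uniformly
    from the tied classes using ``rng``.
    """
    classes = tuple(classes)
    predictions = [str(p) for p in predictions]
    if len(predictions) != len(classes):
        raise ValidationError("one prediction per class member is required")
    unknown = set(predictions) - set(classes)
    if unknown:
        raise ValidationError(f"predictions outside the class set: {sorted(unknown)}")

    votes = {c: 0 for c in classes}
    for p in predictions:
        votes[p] += 1
    self_voted = [c for i, c in enumerate(classes) if predictions[i] == c]

    if len(self_voted) == 1:
        return PredictionOutcome(self_voted[0], "self_vote_unique", votes)

    pool = self_voted if self_voted else list(classes)
    rule = "self_vote_majority" if self_voted else "plain_majority"
    best = max(votes[c] for c in pool)
    tied = [c for c in pool if votes[c] == best]
    if len(tied) == 1:
        return PredictionOutcome(tied[0], rule, votes)
    label = tied[int(rng.integers(len(tied)))]
    return PredictionOutcome(label, "random_tie", votes)


def predict(ensemble: EnsembleModel, samples: FeatureMatrix) -> list[PredictionOutcome]:
    """Member-wise prediction followed by the majority cascade, per sample."""
    if samples.feature_ids != ensemble.feature_ids:
        raise ValidationError("samples do not share the training feature space")
    member_preds = [
        clf.predict(samples.values[:, cols]) for _, cols, clf in ensemble.members
    ]
    outcomes = []
    for s in range(samples.n_samples):
        row = [member_preds[i][s] for i in range(len(ensemble.members))]
        outcomes.append(decide_majority(row, ensemble.classes, ensemble.rng))
    return outcomes


def vote_share_matrix(
    outcomes: list[PredictionOutcome], classes
) -> np.ndarray:
    """Per-class vote fractions (rows: samples) — a score surrogate for ROC."""
    classes = tuple(classes)
    c = len(classes)
    out = np.zeros((len(outcomes), c))
    for i, o in enumerate(outcomes):
        for k, cls in enumerate(classes):
            out[i, k] = o.votes.get(cls, 0) / c
    return out
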