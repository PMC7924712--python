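"""Synthetic fixtures with the structure the selectors assume.

Two generators: matrices whose columns are affine combinations of a
known representative subset (self-expressive structure), and
high-dimensional multi-class data with disjoint class-specific
informative feature blocks and optional imbalance.  Both are pure
functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from smbacsfs.core_smba import FeatureMatrix, ValidationError
from smbacsfs.csfs_ensemble import LabeledDataset


@dataclass(frozen=True)
class SelfExpressiveSpec:
    m: int = 30
    n_rep: int = 5
    n_dep: int = 35
    noise_sd: float = 0.0
    weight_concentration: float = 1.0
    signed_weights: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n_rep < 1 or self.n_dep < 0:
            raise ValidationError("m, n_rep must be >= 1 and n_dep >= 0")
        if self.noise_sd < 0 or self.weight_concentration <= 0:
            raise ValidationError("noise_sd >= 0 and weight_concentration > 0 required")


@dataclass(frozen=True)
class MulticlassSpec:
    classes: int = 6
    samples_per_class: tuple[int, ...] = ()
    n_features: int = 500
    informative_per_class: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.classes < 2:
            raise ValidationError("need at least 2 classes")
        spc = tuple(self.samples_per_class) or (20,) * self.classes
        if len(spc) != self.classes or any(s < 1 for s in spc):
            raise ValidationError("samples_per_class must list >= 1 per class")
        if self.classes * self.informative_per_class > self.n_features:
            raise ValidationError("informative blocks exceed the feature count")
        if self.informative_per_class < 1 or self.noise_sd < 0:
            raise ValidationError("informative_per_class >= 1, noise_sd >= 0 required")
        object.__setattr__(self, "samples_per_class", spc)


def generate_self_expressive(
    spec: SelfExpressiveSpec,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Representative columns iid N(0,1); dependents are affine combos.

    Dependent weights are Dirichlet draws (sum to one, matching the
    unit-column-sum constraint of the model); ``signed_weights`` swaps
    in signed weights still summing to one for harder instances.
    Returns the matrix and the ground-truth representative indices.
    """
    rng = np.random.default_rng(spec.seed)
    reps = rng.standard_normal((spec.m, spec.n_rep))
    if spec.n_dep:
        if spec.signed_weights:
            w = rng.standard_normal((spec.n_rep, spec.n_dep))
            w /= w.sum(axis=0, keepdims=True)
        else:
            w = rng.dirichlet(
                [spec.weight_concentration] * spec.n_rep, size=spec.n_dep
            ).T
        deps = reps @ w
        if spec.noise_sd > 0:
            deps = deps + spec.noise_sd * rng.standard_normal(deps.shape)
        values = np.hstack([reps, deps])
    else:
        values = reps
    matrix = FeatureMatrix.from_array(values)
    return matrix, np.arange(spec.n_rep)


def generate_multiclass(
    spec: MulticlassSpec,
) -> tuple[LabeledDataset, dict[str, np.ndarray]]:
    """Gaussian background with a mean shift on each class's own block.

    Class ``i`` occupies the feature block ``[i*b, (i+1)*b)``; its
    samples are shifted there by ``effect_size`` (in baseline-sd units).
    Returns the labeled dataset and the per-class ground-truth indices.
    """
    rng = np.random.default_rng(spec.seed)
    total = sum(spec.samples_per_class)
    values = spec.noise_sd * rng.standard_normal((total, spec.n_features))
    labels: list[str] = []
    truth: dict[str, np.ndarray] = {}
    b = spec.informative_per_class
    row = 0
    for i, count in enumerate(spec.samples_per_class):
        label = f"c{i}"
        block = np.arange(i * b, (i + 1) * b)
        values[row : row + count, block] += spec.effect_size
        labels.extend([label] * count)
        truth[label] = block
        row += count
    dataset = LabeledDataset(
        matrix=FeatureMatrix.from_array(values), labels=tuple(labels)
    )
    return dataset, truth
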