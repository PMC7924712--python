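"""Affine-constrained row-sparse self-representation solved by ADMM.

The model expresses every feature (column) of a data matrix as an affine
combination of a small set of representative features, by minimizing

    (1/2) * ||X - X C||_F^2 + lam * sum_i ||c^i||_q    s.t.  1^T C = 1^T

over the n x n coefficient matrix ``C`` (``c^i`` is the i-th row).  The
row-sparsity penalty drives entire rows of ``C`` to zero; the surviving
rows index the representative features, and their row norms rank them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

logger = logging.getLogger(__name__)

#: row-norm orders supported by the penalty
_SUPPORTED_Q = (2.0, math.inf)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateDataError(ValueError):
    """Raised when the data carries no usable signal (e.g. constant X)."""


class EmptySelectionError(ValueError):
    """Raised when a selection step returns no features (lambda too large)."""


def _normalize_q(q) -> float:
    qf = float(q) if q != "inf" else math.inf
    if qf not in _SUPPORTED_Q:
        raise ValidationError(f"q must be 2 or inf, got {q!r}")
    return qf


def _row_norms(M: np.ndarray, q: float) -> np.ndarray:
    if q == math.inf:
        return np.abs(M).max(axis=1) if M.shape[1] else np.zeros(M.shape[0])
    return np.linalg.norm(M, ord=2, axis=1)


@dataclass(frozen=True)
class FeatureMatrix:
    """Real-valued expression matrix, samples as rows, features as columns."""

    values: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError("matrix must have at least one sample and one feature")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite entry at sample {bad[0]}, feature {bad[1]}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if len(self.feature_ids) != values.shape[1]:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {values.shape[1]} columns"
            )
        if len(self.sample_ids) != values.shape[0]:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {values.shape[0]} rows"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values, feature_ids=None, sample_ids=None) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        m, n = values.shape
        if feature_ids is None:
            feature_ids = tuple(f"f{j}" for j in range(n))
        if sample_ids is None:
            sample_ids = tuple(f"s{i}" for i in range(m))
        return cls(values=values, feature_ids=tuple(feature_ids), sample_ids=tuple(sample_ids))

    def subset_samples(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[idx],
            feature_ids=self.feature_ids,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )

    def subset_features(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_ids=tuple(self.feature_ids[i] for i in idx),
            sample_ids=self.sample_ids,
        )


@dataclass(frozen=True)
class SMBAParams:
    """Solver parameters.

    Exactly one of ``lam`` (the penalty weight) or ``alpha`` (a
    dimensionless divisor, ``lam = lambda_reference(X) / alpha``) must be
    set; ``alpha=2`` is the default when neither is given.
    """

    lam: float | None = None
    alpha: float | None = None
    rho: float | None = 1.0
    delta: float = 1e-5
    eta: float = 1e-4
    q: float = 2.0
    max_iter: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.lam is not None and self.alpha is not None:
            raise ValidationError("set exactly one of lam / alpha")
        if self.lam is None and self.alpha is None:
            object.__setattr__(self, "alpha", 2.0)
        if self.lam is not None and self.lam <= 0:
            raise ValidationError("lam must be > 0")
        if self.alpha is not None and self.alpha <= 1:
            raise ValidationError("alpha must be > 1")
        if self.rho is not None and self.rho <= 0:
            raise ValidationError("rho must be > 0 (or None to match lam)")
        if self.delta <= 0:
            raise ValidationError("delta must be > 0")
        if not 0 <= self.eta < 1:
            raise ValidationError("eta must lie in [0, 1)")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be a positive integer")
        object.__setattr__(self, "q", _normalize_q(self.q))

    def resolve_lam(self, X: FeatureMatrix) -> float:
        if self.lam is not None:
            return float(self.lam)
        return lambda_reference(X, q=self.q) / float(self.alpha)


@dataclass
class ADMMState:
    """Iterate of the ADMM loop (scaled-dual form)."""

    beta: np.ndarray
    theta: np.ndarray
    mu: np.ndarray
    t: int = 0
    epsilon: float = math.inf

    def __post_init__(self):
        if not (self.beta.shape == self.theta.shape == self.mu.shape):
            raise ValidationError("beta, theta, mu must share a shape")
        if self.t < 0 or self.epsilon < 0:
            raise ValidationError("t and epsilon must be nonnegative")


@dataclass(frozen=True)
class CoefficientMatrix:
    """Converged self-representation coefficients plus solver metadata."""

    C: np.ndarray
    row_norms: np.ndarray
    objective: float
    constraint_residual: float
    converged: bool
    iterations: int
    feature_ids: tuple[str, ...]
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_features(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by decreasing coefficient-row norm."""

    order: np.ndarray
    scores: np.ndarray
    feature_ids: tuple[str, ...]

    def __post_init__(self):
        order = np.asarray(self.order, dtype=int)
        scores = np.asarray(self.scores, dtype=float)
        if len(set(order.tolist())) != order.size:
            raise ValidationError("order contains duplicates")
        if np.any(np.diff(scores) > 1e-12):
            raise ValidationError("scores must be non-increasing")
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "scores", scores)

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def __len__(self) -> int:
        return self.order.size


def compute_objective(X: FeatureMatrix, C: np.ndarray, lam: float, q=2) -> float:
    """Value of the penalized self-representation objective at ``C``."""
    q = _normalize_q(q)
    C = np.asarray(C, dtype=float)
    n = X.n_features
    if C.shape != (n, n):
        raise ValidationError(f"C must be {n}x{n}, got {C.shape}")
    if not np.isfinite(C).all():
        raise ValidationError("C contains non-finite entries")
    if lam < 0:
        raise ValidationError("lam must be nonnegative")
    V = X.values
    fit = 0.5 * float(np.linalg.norm(V - V @ C, "fro") ** 2)
    penalty = lam * float(_row_norms(C, q).sum())
    return fit + penalty


def _project_l1_ball(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection onto the l1 ball of the given radius."""
    if radius <= 0:
        return np.zeros_like(v)
    a = np.abs(v)
    if a.sum() <= radius:
        return v.copy()
    u = np.sort(a)[::-1]
    css = np.cumsum(u)
    ks = np.arange(1, a.size + 1)
    rho_idx = np.nonzero(u * ks > css - radius)[0][-1]
    tau = (css[rho_idx] - radius) / (rho_idx + 1.0)
    return np.sign(v) * np.maximum(a - tau, 0.0)


def block_soft_threshold(M: np.ndarray, kappa: float, q=2) -> np.ndarray:
    """Row-wise proximal operator of ``kappa * ||row||_q``.

    For q=2 each row shrinks toward zero by ``kappa`` in norm (and maps
    to zero at or below the threshold).  For q=inf the prox subtracts
    the projection of the row onto the l1 ball of radius ``kappa``.
    """
    q = _normalize_q(q)
    if kappa < 0:
        raise ValidationError("kappa must be nonnegative")
    M = np.asarray(M, dtype=float)
    if kappa == 0:
        return M.copy()
    if q == math.inf:
        out = np.empty_like(M)
        for i in range(M.shape[0]):
            out[i] = M[i] - _project_l1_ball(M[i], kappa)
        return out
    norms = np.linalg.norm(M, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > kappa
    scale[nz] = 1.0 - kappa / norms[nz]
    return M * scale[:, None]


class _AffineQuadraticSolver:
    """Equality-constrained quadratic subproblem, factored once.

    Minimizes ``(1/2)||X - X beta||_F^2 + (rho/2)||beta - T||_F^2``
    subject to unit column sums, via the KKT system

        [ G + rho I   1 ] [ beta_j ]   [ rhs_j ]
        [   1^T       0 ] [  nu_j  ] = [   1   ]

    where ``G = X^T X`` and ``rhs = G + rho*theta - mu``.  The (n+1)
    square KKT matrix is constant across ADMM iterations, so its LU
    factorization is computed once and reused.
    """

    def __init__(self, gram: np.ndarray, rho: float):
        gram = np.asarray(gram, dtype=float)
        n = gram.shape[0]
        if gram.shape != (n, n):
            raise ValidationError("gram must be square")
        if rho <= 0:
            raise np.linalg.LinAlgError("rho must be positive for a nonsingular KKT system")
        kkt = np.zeros((n + 1, n + 1))
        kkt[:n, :n] = gram + rho * np.eye(n)
        kkt[:n, n] = 1.0
        kkt[n, :n] = 1.0
        self.n = n
        self._lu = lu_factor(kkt)

    def solve(self, target: np.ndarray) -> np.ndarray:
        n = self.n
        rhs = np.ones((n + 1, n))
        rhs[:n, :] = target
        sol = lu_solve(self._lu, rhs)
        return sol[:n, :]


def solve_beta_subproblem(gram: np.ndarray, target: np.ndarray, rho: float) -> np.ndarray:
    """One-shot wrapper around the factored KKT solve.

    ``target`` is the stationarity right-hand side
    ``rho*theta - mu + gram`` (columnwise).
    """
    return _AffineQuadraticSolver(gram, rho).solve(np.asarray(target, dtype=float))


def solve_smba(X: FeatureMatrix, params: SMBAParams) -> CoefficientMatrix:
    """Run ADMM on the penalized self-representation problem.

    Alternates the affine-constrained quadratic update of ``beta``, the
    row-wise shrinkage of ``theta``, and the dual ascent on ``mu``;
    stops when the relative primal residual drops to ``params.delta``
    or at ``params.max_iter``.  The returned coefficients come from the
    ``theta`` block, whose rows are exactly sparse.
    """
    n = X.n_features
    lam = params.resolve_lam(X)
    # rho=None matches the penalty scale; constant within a solve, so the
    # KKT factorization is still computed once
    rho = lam if params.rho is None else params.rho
    V = X.values
    gram = V.T @ V

    solver = _AffineQuadraticSolver(gram, rho)
    state = ADMMState(
        beta=np.zeros((n, n)), theta=np.zeros((n, n)), mu=np.zeros((n, n))
    )
    residuals: list[float] = []
    converged = False
    for t in range(1, params.max_iter + 1):
        beta = solver.solve(gram + rho * state.theta - state.mu)
        theta = block_soft_threshold(beta + state.mu / rho, lam / rho, params.q)
        mu = state.mu + rho * (beta - theta)
        eps = np.linalg.norm(beta - theta, "fro") / max(1.0, np.linalg.norm(beta, "fro"))
        state = ADMMState(beta=beta, theta=theta, mu=mu, t=t, epsilon=eps)
        residuals.append(eps)
        if eps <= params.delta:
            converged = True
            break
    if not converged:
        logger.warning(
            "ADMM did not converge in %d iterations (residual %.3e > delta %.3e)",
            params.max_iter, state.epsilon, params.delta,
        )

    C = state.theta
    col_sums = C.sum(axis=0)
    return CoefficientMatrix(
        C=C,
        row_norms=_row_norms(C, params.q),
        objective=compute_objective(X, C, lam, params.q),
        constraint_residual=float(np.abs(col_sums - 1.0).max()),
        converged=converged,
        iterations=state.t,
        feature_ids=X.feature_ids,
        residual_history=np.asarray(residuals),
    )


def rank_features(C: CoefficientMatrix, q=2) -> FeatureRanking:
    """Sort features by decreasing row norm; ties keep original order."""
    q = _normalize_q(q)
    norms = _row_norms(C.C, q)
    order = np.argsort(-norms, kind="stable")
    return FeatureRanking(
        order=order,
        scores=norms[order],
        feature_ids=tuple(C.feature_ids[i] for i in order),
    )


def find_representatives(C: CoefficientMatrix, eta: float, q=2) -> list[int]:
    """Indices whose relative row norm exceeds ``eta``, ranking order."""
    q = _normalize_q(q)
    if not 0 <= eta < 1:
        raise ValidationError("eta must lie in [0, 1)")
    norms = _row_norms(C.C, q)
    top = norms.max()
    if top <= 0:
        raise EmptySelectionError(
            "all coefficient rows are zero; lambda is too large for this data"
        )
    ranking = rank_features(C, q)
    return [int(i) for i in ranking.order if norms[i] / top > eta]


def lambda_reference(X: FeatureMatrix, q=2) -> float:
    """Data-dependent regularization scale.

    Maximum over features of the dual-norm distance between that
    feature's Gram column and the mean Gram column; homogeneous of
    degree 2 in the data.
    """
    q = _normalize_q(q)
    if X.n_features < 2:
        raise ValidationError("lambda_reference needs at least 2 features")
    gram = X.values.T @ X.values
    centered = gram - gram.mean(axis=1, keepdims=True)
    dual_ord = 2 if q == 2 else 1
    value = float(np.linalg.norm(centered, ord=dual_ord, axis=0).max())
    if value <= 0:
        raise DegenerateDataError("constant data: zero reference scale")
    return value
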