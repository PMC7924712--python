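"""Shared fixtures and independent oracle solvers used across the suite."""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from smbacsfs import FeatureMatrix


def slsqp_oracle(X: FeatureMatrix, lam: float, eps: float = 1e-12) -> np.ndarray:
    """Generic convex solver for the penalized self-representation problem.

    Smooths the row norms as sqrt(||row||^2 + eps) and hands the whole
    problem (vectorized C, per-column unit-sum equality constraints) to
    SLSQP.  Independent of the ADMM path under test.
    """
    V = X.values
    n = X.n_features

    def objective(c):
        C = c.reshape(n, n)
        fit = 0.5 * np.linalg.norm(V - V @ C, "fro") ** 2
        pen = lam * np.sum(np.sqrt(np.sum(C**2, axis=1) + eps))
        return fit + pen

    constraints = [
        {"type": "eq", "fun": (lambda c, j=j: c.reshape(n, n)[:, j].sum() - 1.0)}
        for j in range(n)
    ]
    res = minimize(
        objective,
        np.eye(n).ravel(),
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x.reshape(n, n)


def qp_oracle(gram: np.ndarray, target: np.ndarray, rho: float) -> np.ndarray:
    """Equality-constrained QP minimizer via a generic constrained solver.

    Solves min_b (1/2) b^T (G + rho I) b - t^T b  s.t. 1^T b = 1,
    column by column, with trust-constr (independent of the KKT path).
    """
    n = gram.shape[0]
    H = gram + rho * np.eye(n)
    cols = []
    for j in range(n):
        t = target[:, j]
        res = minimize(
            lambda b: 0.5 * b @ H @ b - t @ b,
            np.full(n, 1.0 / n),
            jac=lambda b: H @ b - t,
            method="trust-constr",
            constraints=[LinearConstraint(np.ones((1, n)), 1.0, 1.0)],
            options={"gtol": 1e-12, "xtol": 1e-14},
        )
        cols.append(res.x)
    return np.column_stack(cols)


def brute_force_majority(predictions, classes, tie_breaker=None):
    """Literal reimplementation of the cascaded decision rule.

    Returns (winner_or_tied_set, rule_path).  When the rule ends in a
    random draw the full tied set is returned instead of a single label.
    """
    predictions = list(predictions)
    classes = list(classes)
    votes = {c: sum(1 for p in predictions if p == c) for c in classes}
    self_votes = [c for i, c in enumerate(classes) if predictions[i] == c]
    if len(self_votes) == 1:
        return self_votes[0], "self_vote_unique"
    pool = self_votes if self_votes else classes
    rule = "self_vote_majority" if self_votes else "plain_majority"
    best = max(votes[c] for c in pool)
    tied = [c for c in pool if votes[c] == best]
    if len(tied) == 1:
        return tied[0], rule
    return set(tied), "random_tie"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    return FeatureMatrix.from_array(rng.standard_normal((6, 4)))
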