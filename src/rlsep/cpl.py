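"""Convex piecewise-linear (CPL) criterion functions and their exact
minimization.

The perceptron criterion of a hyperplane H(w, theta) over two learning sets
is a weighted sum of hinge penalties,

    phi_j(w, theta) = max(0, delta - y_j (w . x_j - theta))
    Phi(w, theta)   = sum_j alpha_j phi_j(w, theta),

which is zero exactly at hyperplanes separating G+ from G- with margin
delta. Feature selection uses the modified criterion

    Psi_lambda(w, theta) = Phi(w, theta) + lambda sum_i gamma_i |w_i|,

whose L1 cost term drives weight components to exact zero as the cost level
lambda grows. Both criteria are convex piecewise-linear, so their global
minimum is found exactly by linear programming: hinge terms become slack
variables and each |w_i| splits into positive/negative parts. The threshold
theta carries no cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .datamodel import CplSpec, FeatureSubspace, LabeledDataset, LinearClassifier

__all__ = [
    "CplSolution",
    "phi",
    "psi",
    "minimize_cpl",
    "is_linearly_separable",
    "ZERO_TOL",
    "SEP_TOL",
]

#: absolute tolerance below which an optimal weight counts as exactly zero
ZERO_TOL = 1e-8
#: objective tolerance below which the learning sets count as separable
SEP_TOL = 1e-7


@dataclass(frozen=True)
class CplSolution:
    """Result of one exact CPL minimization."""

    classifier: LinearClassifier
    objective: float
    zero_weight_indices: tuple[int, ...]  # subspace-relative positions
    iterations: int
    status: str

    @property
    def nonzero_subspace(self) -> FeatureSubspace:
        zero = set(self.zero_weight_indices)
        kept = tuple(
            idx for pos, idx in enumerate(self.classifier.subspace.indices)
            if pos not in zero
        )
        return FeatureSubspace(kept)


def phi(classifier: LinearClassifier, dataset: LabeledDataset,
        spec: CplSpec = CplSpec()) -> float:
    """Perceptron criterion Phi: weighted sum of margin-hinge penalties.

    Zero iff every patient meets its margin: y_j (w.x_j - theta) >= delta.
    """
    alpha = spec.resolve_alpha(dataset.y)
    scores = classifier.decision_scores(dataset.X)
    hinges = np.maximum(0.0, spec.delta - dataset.y * scores)
    return float(alpha @ hinges)


def psi(classifier: LinearClassifier, dataset: LabeledDataset,
        spec: CplSpec = CplSpec()) -> float:
    """Modified criterion Psi_lambda = Phi + lambda * sum_i gamma_i |w_i|.

    The threshold theta is never penalized; at lambda = 0 this is Phi.
    """
    gamma = spec.resolve_gamma(classifier.subspace.dimension)
    cost = float(gamma @ np.abs(classifier.weights))
    return phi(classifier, dataset, spec) + spec.lam * cost


def _solve_lp(X: np.ndarray, y: np.ndarray, alpha: np.ndarray,
              gamma: np.ndarray, lam: float, delta: float):
    """Exact LP for min Psi_lambda. Variables [u, v, theta, xi] with
    w = u - v, u,v >= 0, xi_j >= hinge_j >= 0, theta free."""
    m, k = X.shape
    c = np.concatenate([lam * gamma, lam * gamma, [0.0], alpha])
    A = np.empty((m, 2 * k + 1 + m))
    yx = y[:, None] * X
    A[:, :k] = -yx
    A[:, k:2 * k] = yx
    A[:, 2 * k] = y
    A[:, 2 * k + 1:] = -np.eye(m)
    b = np.full(m, -delta)
    bounds = [(0, None)] * (2 * k) + [(None, None)] + [(0, None)] * m
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    return res, k


def minimize_cpl(dataset: LabeledDataset, spec: CplSpec = CplSpec(),
                 subspace: FeatureSubspace | None = None) -> CplSolution:
    """Globally minimize Psi_lambda over a feature subspace.

    The criterion is convex piecewise-linear, so the minimization reduces
    to a linear program over hinge slacks and |w_i| split variables and is
    exact up to LP solver tolerance. LP vertex solutions give exact zero
    weights; the reported zero set uses an absolute tolerance to guard
    floating point.
    """
    if subspace is None:
        subspace = FeatureSubspace.full(dataset.n)
    if subspace.dimension == 0:
        raise ValueError("subspace must contain at least one feature")
    if max(subspace.indices) >= dataset.n:
        raise ValueError("subspace index out of range for dataset")

    idx = list(subspace.indices)
    X = dataset.X[:, idx]
    if np.isnan(X).any():
        raise ValueError("dataset contains missing values; impute before fitting")

    alpha = spec.resolve_alpha(dataset.y)
    gamma = spec.resolve_gamma(subspace.dimension)
    res, k = _solve_lp(X, dataset.y, alpha, gamma, spec.lam, spec.delta)
    if res.status != 0:
        raise RuntimeError(f"LP solver failed (status {res.status}): {res.message}")

    w = res.x[:k] - res.x[k:2 * k]
    theta = float(res.x[2 * k])
    w = np.where(np.abs(w) <= ZERO_TOL, 0.0, w)
    zeros = tuple(int(i) for i in np.flatnonzero(w == 0.0))
    clf = LinearClassifier(weights=w, threshold=theta, subspace=subspace)
    return CplSolution(
        classifier=clf,
        objective=max(float(res.fun), 0.0),
        zero_weight_indices=zeros,
        iterations=int(getattr(res, "nit", 0)),
        status="optimal",
    )


def is_linearly_separable(dataset: LabeledDataset,
                          subspace: FeatureSubspace | None = None) -> bool:
    """True iff a hyperplane puts G+ strictly on one side and G- on the
    other, i.e. the perceptron criterion minimum (lambda = 0) is zero."""
    sol = minimize_cpl(dataset, CplSpec(lam=0.0), subspace)
    return sol.objective <= SEP_TOL
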