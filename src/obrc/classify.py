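"""Classifiers: Bayes decision rule with known parameters, the optimal
Bayesian risk classifier (OBRC), plug-in LDA/QDA baselines, and explicit
linear / per-bin classifiers.

Every classifier exposes ``predict(X) -> labels`` with deterministic
tie-breaking to the lowest class index.  The OBRC minimizes the Bayesian
conditional risk estimate pointwise, which reduces to choosing the class
``i`` minimizing ``sum_y lambda(i, y) E[C_y | S] f(x | y, S)`` with the
effective densities in place of the unknown true ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .densities import Categorical, Gaussian, effective_density
from .models import ClassProbPosterior, LossMatrix

__all__ = [
    "LinearClassifier",
    "BinClassifier",
    "BayesDecisionRule",
    "OBRC",
    "bdr_predict",
    "posterior_class_prob",
    "bcre",
    "obrc_predict",
    "plugin_lda",
    "plugin_qda",
]


@dataclass(frozen=True)
class LinearClassifier:
    """Binary rule predicting 0 when ``g(x) = a^T x + b <= 0``, else 1."""

    a: np.ndarray
    b: float

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if not np.any(a != 0):
            raise ValueError("weight vector must not be all zero")
        object.__setattr__(self, "a", a)

    def g(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.a + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.g(X) > 0).astype(int)


@dataclass(frozen=True)
class BinClassifier:
    """Explicit label assignment per discrete bin (bins are ``1..b``)."""

    assignments: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.assignments)[np.asarray(x, dtype=int) - 1]


def _risk_scores(log_densities: np.ndarray, weights: np.ndarray, loss: LossMatrix) -> np.ndarray:
    """Unnormalized conditional-risk scores, shape (n, M).

    ``log_densities[n, y]`` are per-class log densities at each point; the
    row maximum is factored out so underflow at D=20 cannot zero out the
    comparison.  Rows where every density underflows to -inf fall back to
    the prior-weighted loss (a data-free decision, never NaN).
    """
    L = np.atleast_2d(log_densities)
    row_max = L.max(axis=1, keepdims=True)
    degenerate = ~np.isfinite(row_max[:, 0])
    shifted = np.where(np.isfinite(row_max), L - row_max, 0.0)
    f = np.exp(shifted) * weights
    scores = f @ loss.matrix.T
    if np.any(degenerate):
        scores[degenerate] = weights @ loss.matrix.T
    return scores


def _log_density_matrix(densities: Sequence, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if isinstance(densities[0], Categorical):
        pts = np.atleast_1d(X)
    else:
        pts = np.atleast_2d(X)
    return np.stack([np.atleast_1d(d.logpdf(pts)) for d in densities], axis=1)


@dataclass(frozen=True)
class BayesDecisionRule:
    """Minimum-conditional-risk classifier for known ``(c, theta)``."""

    c: np.ndarray
    densities: tuple
    loss: LossMatrix

    def predict(self, X: np.ndarray) -> np.ndarray:
        L = _log_density_matrix(self.densities, X)
        return np.argmin(_risk_scores(L, np.asarray(self.c, float), self.loss), axis=1)


def bdr_predict(x, c, densities: Sequence, loss: LossMatrix) -> np.ndarray:
    """Bayes decision rule labels for points ``x`` with known parameters."""
    return BayesDecisionRule(np.asarray(c, float), tuple(densities), loss).predict(x)


class OBRC:
    """Optimal Bayesian risk classifier for a (class-prob, model) posterior."""

    def __init__(self, class_prob: ClassProbPosterior, posterior, loss: LossMatrix):
        if class_prob.n_classes != loss.n_classes:
            raise ValueError("class-probability posterior and loss disagree on M")
        self.class_prob = class_prob
        self.posterior = posterior
        self.loss = loss
        self._weights = class_prob.mean()
        self._densities = tuple(
            effective_density(posterior, y) for y in range(class_prob.n_classes)
        )

    @property
    def effective_densities(self) -> tuple:
        return self._densities

    def predict(self, X: np.ndarray) -> np.ndarray:
        L = _log_density_matrix(self._densities, X)
        return np.argmin(_risk_scores(L, self._weights, self.loss), axis=1)

    def posterior_class_prob(self, X: np.ndarray) -> np.ndarray:
        """``f(y | x, S)`` for each point, shape (n, M)."""
        L = _log_density_matrix(self._densities, X)
        row_max = L.max(axis=1, keepdims=True)
        if np.any(~np.isfinite(row_max)):
            raise ValueError("all effective densities are zero at some query point")
        f = np.exp(L - row_max) * self._weights
        total = f.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise ValueError("all effective densities are zero at some query point")
        return f / total

    def bcre(self, X: np.ndarray) -> np.ndarray:
        """Bayesian conditional risk estimate per prediction, shape (n, M)."""
        return self.posterior_class_prob(X) @ self.loss.matrix.T


def posterior_class_prob(x, class_prob: ClassProbPosterior, posterior, loss=None) -> np.ndarray:
    M = class_prob.n_classes
    return OBRC(class_prob, posterior, loss or LossMatrix.zero_one(M)).posterior_class_prob(x)


def bcre(x, class_prob: ClassProbPosterior, posterior, loss: LossMatrix) -> np.ndarray:
    return OBRC(class_prob, posterior, loss).bcre(x)


def obrc_predict(x, class_prob: ClassProbPosterior, posterior, loss: LossMatrix) -> np.ndarray:
    return OBRC(class_prob, posterior, loss).predict(x)


def _empirical_class_probs(labels: np.ndarray, M: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=M).astype(float)
    return counts / counts.sum()


def _check_pd(cov: np.ndarray, context: str) -> None:
    tol = 1e-10 * max(float(np.trace(cov)), 1e-30)
    if np.linalg.eigvalsh(cov).min() <= tol:
        raise ValueError(f"singular covariance estimate in {context}")


def plugin_lda(X: np.ndarray, labels: np.ndarray, loss: LossMatrix, class_probs=None) -> BayesDecisionRule:
    """Plug-in rule with sample means and the pooled sample covariance."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    M = loss.n_classes
    n, D = X.shape
    if n < M + 1:
        raise ValueError("LDA requires at least M + 1 training points")
    means, pooled = [], np.zeros((D, D))
    for y in range(M):
        block = X[labels == y]
        if block.shape[0] == 0:
            raise ValueError(f"LDA undefined: no training points in class {y}")
        means.append(block.mean(axis=0))
        if block.shape[0] > 1:
            pooled += (block.shape[0] - 1) * np.cov(block, rowvar=False, ddof=1).reshape(D, D)
    pooled /= max(n - M, 1)
    _check_pd(pooled, "LDA pooled covariance")
    c = _empirical_class_probs(labels, M) if class_probs is None else np.asarray(class_probs, float)
    return BayesDecisionRule(c, tuple(Gaussian(m, pooled) for m in means), loss)


def plugin_qda(X: np.ndarray, labels: np.ndarray, loss: LossMatrix, class_probs=None) -> BayesDecisionRule:
    """Plug-in rule with sample means and per-class sample covariances."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    M = loss.n_classes
    D = X.shape[1]
    dens = []
    for y in range(M):
        block = X[labels == y]
        if block.shape[0] < 2:
            raise ValueError(f"QDA undefined: class {y} has fewer than 2 training points")
        cov = np.cov(block, rowvar=False, ddof=1).reshape(D, D)
        _check_pd(cov, f"QDA class {y} covariance")
        dens.append(Gaussian(block.mean(axis=0), cov))
    c = _empirical_class_probs(labels, M) if class_probs is None else np.asarray(class_probs, float)
    return BayesDecisionRule(c, tuple(dens), loss)
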