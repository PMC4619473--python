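"""Expected risk under known parameters, Bayesian risk estimation (BRE),
and classical resampling risk estimators (cross-validation, leave-one-out,
0.632 bootstrap).

The BRE is the posterior-mean expected risk: ``sum_{y,i} lambda(i, y)
f(y | S) eps_hat^{i,y}`` where ``eps_hat^{i,y}`` is the posterior
probability that a class-y point lands in decision region ``Gamma_i``.
Closed forms exist for the discrete model under any classifier and for the
Gaussian models under binary linear classifiers; everything else is
approximated by sampling the effective densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import BinClassifier, LinearClassifier
from .densities import Categorical, Gaussian, effective_density, sample_effective
from .models import (
    ClassProbPosterior,
    DiscretePosterior,
    GaussianPosterior,
    LossMatrix,
    class_prob_moments,
    linear_gaussian_summary,
)
from .numerics import std_normal_cdf, t_cdf_at_zero

logger = logging.getLogger(__name__)

__all__ = [
    "TrueRisk",
    "RiskReport",
    "ClassicalRiskEstimate",
    "true_risk",
    "eps_hat",
    "eps_hat_from_draws",
    "bre",
    "classical_risk_estimate",
    "empirical_risk",
]


@dataclass(frozen=True)
class TrueRisk:
    """Expected risk of a classifier under a known feature-label law."""

    value: float
    eps: np.ndarray  # eps[i, y] = P(assigned i | truth y)
    method: str  # "closed" | "monte_carlo"
    n_test: int | None = None
    mc_rms_bound: float | None = None

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class RiskReport:
    """BRE together with its building blocks and optional conditional MSE."""

    bre: float
    eps_hat: np.ndarray
    class_first_moment: np.ndarray
    class_second_moment: np.ndarray
    method: str
    mse: float | None = None
    rms: float | None = None
    n_mc: int | None = None
    seed: int | None = None

    def __float__(self) -> float:
        return self.bre


@dataclass(frozen=True)
class ClassicalRiskEstimate:
    value: float
    method: str
    n_used: int
    n_skipped: int = 0

    def __float__(self) -> float:
        return self.value


def _stratified_counts(c: np.ndarray, n_total: int) -> np.ndarray:
    """Integer per-class test counts proportional to c (largest remainders)."""
    raw = np.asarray(c, float) * n_total
    counts = np.floor(raw).astype(int)
    short = n_total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _loss_risk(eps: np.ndarray, c: np.ndarray, loss: LossMatrix) -> float:
    return float(np.sum(loss.matrix * eps * np.asarray(c, float)[None, :]))


def true_risk(
    classifier,
    c,
    densities,
    loss: LossMatrix,
    method: str = "closed",
    n_test: int = 10_000,
    seed=None,
) -> TrueRisk:
    """Expected risk under the true distribution ``(c, theta)``.

    Closed forms cover binary linear classifiers over Gaussian densities
    (normal CDF of the signed margin) and categorical densities with any
    classifier (finite sum over bins).  The Monte Carlo path draws a
    stratified test sample and reports the ``1 / sqrt(4 n_test)`` RMS bound
    of the resulting approximation.
    """
    c = np.asarray(c, float)
    M = loss.n_classes
    if method == "closed":
        if all(isinstance(d, Categorical) for d in densities):
            b = densities[0].probs.shape[0]
            assigned = np.asarray(classifier.predict(np.arange(1, b + 1)))
            eps = np.zeros((M, M))
            for y, d in enumerate(densities):
                for i in range(M):
                    eps[i, y] = d.probs[assigned == i].sum()
            return TrueRisk(_loss_risk(eps, c, loss), eps, "closed")
        if isinstance(classifier, LinearClassifier) and all(
            isinstance(d, Gaussian) for d in densities
        ):
            if M != 2:
                raise ValueError("closed-form linear risk requires M = 2")
            eps = np.zeros((2, 2))
            for y, d in enumerate(densities):
                g_mu = float(classifier.a @ d.mean_vec + classifier.b)
                s = float(np.sqrt(classifier.a @ d.covariance() @ classifier.a))
                for i in range(2):
                    eps[i, y] = std_normal_cdf(-((-1.0) ** i) * g_mu / s)
            return TrueRisk(_loss_risk(eps, c, loss), eps, "closed")
        raise ValueError("no closed form for this classifier/density pair; use method='mc'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _stratified_counts(c, n_test)
    eps = np.zeros((M, M))
    for y, d in enumerate(densities):
        if counts[y] == 0:
            continue
        draws = d.rvs(int(counts[y]), rng)
        assigned = np.asarray(classifier.predict(draws))
        eps[:, y] = np.bincount(assigned, minlength=M) / counts[y]
    bound = 1.0 / (2.0 * np.sqrt(n_test))
    return TrueRisk(_loss_risk(eps, c, loss), eps, "monte_carlo", n_test, bound)


def _eps_hat_closed(classifier, post) -> np.ndarray:
    if isinstance(post, DiscretePosterior):
        M = post.n_classes
        b = post.n_bins
        assigned = np.asarray(classifier.predict(np.arange(1, b + 1)))
        eps = np.zeros((M, M))
        for y in range(M):
            probs = post.alpha[y] / post.alpha[y].sum()
            for i in range(M):
                eps[i, y] = probs[assigned == i].sum()
        return eps
    if not isinstance(classifier, LinearClassifier):
        raise ValueError("closed-form eps_hat for Gaussian models requires a binary linear classifier")
    if post.n_classes != 2:
        raise ValueError("closed-form Gaussian eps_hat requires M = 2")
    eps = np.zeros((2, 2))
    for y in range(2):
        for i in range(2):
            s = linear_gaussian_summary(post, y, classifier.a, classifier.b, i)
            if np.isinf(s.k):
                z = -s.m_iy / np.sqrt(s.gamma2 * (s.nu_star + 1.0) / s.nu_star)
                eps[i, y] = std_normal_cdf(z)
            else:
                scale = (s.nu_star + 1.0) / (s.k * s.nu_star) * s.gamma2
                eps[i, y] = t_cdf_at_zero(s.m_iy, scale, s.k)
    return eps


def eps_hat_from_draws(classifier, draws_by_class, n_classes: int) -> np.ndarray:
    """Monte Carlo eps_hat from pre-drawn effective-density samples, so one
    set of draws can score many classifiers."""
    eps = np.zeros((n_classes, n_classes))
    for y, draws in enumerate(draws_by_class):
        assigned = np.asarray(classifier.predict(draws))
        eps[:, y] = np.bincount(assigned, minlength=n_classes) / len(draws)
    return eps


def eps_hat(
    classifier,
    post,
    method: str = "closed",
    n_mc: int = 1_000_000,
    seed=None,
) -> np.ndarray:
    """Posterior probabilities ``eps_hat[i, y]`` of assigning a class-y point
    to class i; each column sums to 1."""
    if method == "closed":
        return _eps_hat_closed(classifier, post)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = post.n_classes
    draws = [sample_effective(effective_density(post, y), n_mc, rng) for y in range(M)]
    return eps_hat_from_draws(classifier, draws, M)


def bre(
    classifier,
    class_prob: ClassProbPosterior,
    post,
    loss: LossMatrix,
    method: str = "closed",
    n_mc: int = 1_000_000,
    seed=None,
) -> RiskReport:
    """Bayesian risk estimator of ``classifier`` under the posterior."""
    first, second = class_prob_moments(class_prob)
    eps = eps_hat(classifier, post, method=method, n_mc=n_mc, seed=seed)
    value = float(np.sum(loss.matrix * eps * first[None, :]))
    return RiskReport(
        bre=value,
        eps_hat=eps,
        class_first_moment=first,
        class_second_moment=second,
        method=method,
        n_mc=None if method == "closed" else n_mc,
        seed=None if not isinstance(seed, (int, np.integer)) else int(seed),
    )


def empirical_risk(classifier, X: np.ndarray, labels: np.ndarray, loss: LossMatrix) -> float:
    """Average loss of the classifier on a labeled set."""
    predicted = np.asarray(classifier.predict(X))
    return float(loss.matrix[predicted, np.asarray(labels)].mean())


def _cv_estimate(X, labels, rule, loss, folds, reps, rng):
    fold_risks, skipped = [], 0
    for _ in range(reps):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        for train_idx, test_idx in splitter.split(X, labels):
            try:
                clf = rule(X[train_idx], labels[train_idx])
            except ValueError:
                skipped += 1
                continue
            fold_risks.append(empirical_risk(clf, X[test_idx], labels[test_idx], loss))
    return fold_risks, skipped


def _loo_estimate(X, labels, rule, loss):
    risks, skipped = [], 0
    n = X.shape[0]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            clf = rule(X[mask], labels[mask])
        except ValueError:
            skipped += 1
            continue
        risks.append(empirical_risk(clf, X[i : i + 1], labels[i : i + 1], loss))
    return risks, skipped


def _boot632_estimate(X, labels, rule, loss, n_boot, rng):
    n = X.shape[0]
    oob_risks, skipped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            skipped += 1
            continue
        try:
            clf = rule(X[idx], labels[idx])
        except ValueError:
            skipped += 1
            continue
        oob_risks.append(empirical_risk(clf, X[oob], labels[oob], loss))
    if not oob_risks:
        raise ValueError("all bootstrap replicates were undefined")
    resub = empirical_risk(rule(X, labels), X, labels, loss)
    value = 0.632 * float(np.mean(oob_risks)) + 0.368 * resub
    return value, len(oob_risks), skipped


def classical_risk_estimate(
    X: np.ndarray,
    labels: np.ndarray,
    rule,
    loss: LossMatrix,
    method: str = "cv",
    folds: int = 10,
    reps: int = 10,
    n_boot: int = 100,
    seed=None,
) -> ClassicalRiskEstimate:
    """Cross-validation, leave-one-out, or 0.632 bootstrap risk estimate.

    ``rule`` is a training procedure ``(X, labels) -> classifier``.  Folds or
    bootstrap replicates on which the rule is undefined (``ValueError``) are
    skipped and counted; an estimate with no usable replicates raises.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "cv":
        risks, skipped = _cv_estimate(X, labels, rule, loss, folds, reps, rng)
    elif method == "loo":
        risks, skipped = _loo_estimate(X, labels, rule, loss)
    elif method == "boot632":
        value, used, skipped = _boot632_estimate(X, labels, rule, loss, n_boot, rng)
        if skipped:
            logger.warning("0.632 bootstrap skipped %d undefined replicates", skipped)
        return ClassicalRiskEstimate(value, "boot632", used, skipped)
    else:
        raise ValueError(f"unknown estimator {method!r}")
    if not risks:
        raise ValueError(f"all {method} replicates were undefined")
    if skipped:
        logger.warning("%s skipped %d undefined folds", method, skipped)
    return ClassicalRiskEstimate(float(np.mean(risks)), method, len(risks), skipped)
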