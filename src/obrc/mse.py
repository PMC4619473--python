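"""Sample-conditioned MSE of the Bayesian risk estimator and of arbitrary
risk estimators.

The conditional MSE is the posterior variance of the true risk around the
BRE.  It decomposes into second moments of the class probabilities and
cross moments ``E[eps^{i,y} eps^{j,z} | S]``, which are probabilities that
an (X, W) pair drawn from the effective *joint* density lands in decision
regions (Gamma_i, Gamma_j).  Closed forms: discrete model (any classifier),
and binary linear classifiers under every Gaussian covariance model —
bivariate normal CDFs for known covariances, bivariate Student t CDFs
otherwise.  The Monte Carlo path pairs each effective-density draw with a
single draw from the effective conditional density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import LinearClassifier
from .densities import effective_density, sample_conditional, sample_effective
from .models import (
    ClassProbPosterior,
    DiscretePosterior,
    GaussianPosterior,
    LossMatrix,
    class_prob_moments,
    linear_gaussian_summary,
)
from .numerics import bvn_cdf, bvt_cdf
from .risk import RiskReport, eps_hat_from_draws

logger = logging.getLogger(__name__)

__all__ = [
    "CrossMomentTable",
    "ConditionedMSE",
    "cross_moment",
    "cross_moment_table",
    "mse_bre",
    "mse_arbitrary",
    "sample_conditional",
]

_NEG_TOL = 1e-10


@dataclass(frozen=True)
class CrossMomentTable:
    """Tensor ``E[eps^{i,y} eps^{j,z} | S]`` indexed ``[i, y, j, z]``."""

    values: np.ndarray
    method: str  # "closed" | "mc"


@dataclass(frozen=True)
class ConditionedMSE:
    mse: float
    rms: float
    report: RiskReport

    def __float__(self) -> float:
        return self.mse


def _pairs_independent(post, y: int, z: int) -> bool:
    """True when Theta_y and Theta_z are a posteriori independent, so the
    cross moment factorizes into a product of eps_hat entries."""
    if y == z:
        return False
    if isinstance(post, DiscretePosterior) or post.structure == "known":
        return True
    return post.coupling == "independent"


def _discrete_pair_table(post: DiscretePosterior, classifier, y: int, eps: np.ndarray) -> np.ndarray:
    a_plus = float(post.alpha[y].sum())
    M = post.n_classes
    e = eps[:, y]
    return (np.outer(e, e) * a_plus + np.diag(e)) / (a_plus + 1.0)


def _gaussian_pair_closed(post: GaussianPosterior, clf: LinearClassifier, y: int, z: int) -> np.ndarray:
    table = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            sy = linear_gaussian_summary(post, y, clf.a, clf.b, i)
            sz = linear_gaussian_summary(post, z, clf.a, clf.b, j)
            if np.isinf(sy.k):  # known covariance, jointly normal margins
                x1 = -sy.m_iy / np.sqrt(sy.gamma2 * (sy.nu_star + 1.0) / sy.nu_star)
                x2 = -sz.m_iy / np.sqrt(sz.gamma2 * (sz.nu_star + 1.0) / sz.nu_star)
                rho = (-1.0) ** (i + j) / (sy.nu_star + 1.0)
                table[i, j] = bvn_cdf(x1, x2, rho)
            else:
                k = sy.k
                x1 = -sy.m_iy * np.sqrt(k * sy.nu_star / ((sy.nu_star + 1.0) * sy.gamma2))
                x2 = -sz.m_iy * np.sqrt(k * sz.nu_star / ((sz.nu_star + 1.0) * sz.gamma2))
                rho = (-1.0) ** (i + j) / (sy.nu_star + 1.0) if y == z else 0.0
                table[i, j] = bvt_cdf(x1, x2, rho, k)
    return table


def _pair_table_mc(post, classifier, y: int, z: int, n_mc: int, rng, xs=None) -> np.ndarray:
    M = post.n_classes
    if xs is None:
        xs = sample_effective(effective_density(post, y), n_mc, rng)
    ws = sample_conditional(post, xs, y, z, rng)
    ix = np.asarray(classifier.predict(xs))
    jw = np.asarray(classifier.predict(ws))
    table = np.zeros((M, M))
    np.add.at(table, (ix, jw), 1.0)
    return table / n_mc


def _eps_and_cross_moments(post, classifier, M: int, method: str, n_mc: int, rng):
    """eps_hat matrix and the full cross-moment tensor from one coherent
    computation: in the MC path the same effective-density draws feed both,
    so the near-cancellation in the MSE decomposition stays stable."""
    values = np.zeros((M, M, M, M))
    draws = None
    if method == "closed":
        from .risk import eps_hat as _eps_hat

        eps = _eps_hat(classifier, post, method="closed")
    else:
        draws = [sample_effective(effective_density(post, y), n_mc, rng) for y in range(M)]
        eps = eps_hat_from_draws(classifier, draws, M)
    for y in range(M):
        for z in range(M):
            if _pairs_independent(post, y, z):
                values[:, y, :, z] = np.outer(eps[:, y], eps[:, z])
            elif method == "closed":
                if isinstance(post, DiscretePosterior):
                    values[:, y, :, z] = _discrete_pair_table(post, classifier, y, eps)
                elif isinstance(classifier, LinearClassifier) and M == 2:
                    values[:, y, :, z] = _gaussian_pair_closed(post, classifier, y, z)
                else:
                    raise ValueError(
                        "closed-form cross moments require the discrete model or a "
                        "binary linear classifier under a Gaussian model; use method='mc'"
                    )
            else:
                # Reuse the eps_hat draws for the y = z pairing, as the MC
                # scheme prescribes; coupled y != z pairs get fresh draws.
                xs = draws[y] if (draws is not None and y == z) else None
                values[:, y, :, z] = _pair_table_mc(post, classifier, y, z, n_mc, rng, xs=xs)
    return eps, values


def cross_moment_table(
    post,
    classifier,
    loss_or_M,
    method: str = "closed",
    n_mc: int = 1_000_000,
    seed=None,
) -> CrossMomentTable:
    """Full cross-moment tensor over (i, y, j, z).

    Pairs with a posteriori independent class parameters factorize into
    products of eps_hat entries; the remaining pairs use the model's closed
    form or effective-joint Monte Carlo.
    """
    M = loss_or_M.n_classes if isinstance(loss_or_M, LossMatrix) else int(loss_or_M)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, values = _eps_and_cross_moments(post, classifier, M, method, n_mc, rng)
    return CrossMomentTable(values, method)


def cross_moment(
    post,
    classifier,
    i: int,
    y: int,
    j: int,
    z: int,
    method: str = "closed",
    n_mc: int = 1_000_000,
    seed=None,
) -> float:
    """Single cross moment ``E[eps^{i,y} eps^{j,z} | S]``."""
    M = post.n_classes
    table = cross_moment_table(post, classifier, M, method=method, n_mc=n_mc, seed=seed)
    return float(table.values[i, y, j, z])


def mse_bre(
    class_prob: ClassProbPosterior,
    post,
    classifier,
    loss: LossMatrix,
    method: str = "closed",
    n_mc: int = 1_000_000,
    seed=None,
) -> ConditionedMSE:
    """Sample-conditioned MSE (and RMS) of the BRE for ``classifier``.

    Assembled from the class-probability second moments, the cross-moment
    tensor, and the BRE itself; tiny negative values from floating-point
    cancellation are clamped to zero with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    first, second = class_prob_moments(class_prob)
    eps, values = _eps_and_cross_moments(post, classifier, loss.n_classes, method, n_mc, rng)
    lam = loss.matrix
    raw = np.einsum("iy,jz,yz,iyjz->", lam, lam, second, values)
    bre_value = float(np.sum(lam * eps * first[None, :]))
    report = RiskReport(
        bre=bre_value,
        eps_hat=eps,
        class_first_moment=first,
        class_second_moment=second,
        method=method,
        n_mc=None if method == "closed" else n_mc,
        seed=None if not isinstance(seed, (int, np.integer)) else int(seed),
    )
    value = float(raw - report.bre**2)
    if value < 0:
        if value < -_NEG_TOL:
            logger.warning("conditional MSE clamped from %.3e to 0", value)
        value = 0.0
    rms = float(np.sqrt(value))
    full = RiskReport(
        bre=report.bre,
        eps_hat=report.eps_hat,
        class_first_moment=first,
        class_second_moment=second,
        method=method,
        mse=value,
        rms=rms,
        n_mc=report.n_mc,
        seed=report.seed,
    )
    return ConditionedMSE(mse=value, rms=rms, report=full)


def mse_arbitrary(
    class_prob: ClassProbPosterior,
    post,
    classifier,
    loss: LossMatrix,
    estimate: float,
    method: str = "closed",
    n_mc: int = 1_000_000,
    seed=None,
) -> float:
    """Conditional MSE of an arbitrary risk estimate:
    ``MSE(R_hat_bullet) = MSE(R_hat) + (R_hat - R_hat_bullet)^2``."""
    base = mse_bre(class_prob, post, classifier, loss, method=method, n_mc=n_mc, seed=seed)
    return base.mse + (base.report.bre - float(estimate)) ** 2
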