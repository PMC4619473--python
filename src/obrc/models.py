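"""Conjugate Bayesian models for class probabilities and class-conditional
densities.

Two families are supported:

* a discrete model on bins ``1..b`` with independent Dirichlet priors on the
  per-class bin probabilities, and
* Gaussian models with normal means and one of three covariance structures
  (``known``, ``arbitrary`` inverse-Wishart, ``scaled_identity``), coupled
  either independently across classes or homoscedastically (one shared
  covariance parameter).

Hyperparameter containers deliberately accept improper priors (for example
``nu = 0`` or small/negative ``kappa``): only the *posterior* is required to
be proper, which is checked wherever a posterior quantity is evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LossMatrix",
    "ClassProbPosterior",
    "DiscretePosterior",
    "GaussianPosterior",
    "LinearGaussianSummary",
    "update_class_prob",
    "class_prob_moments",
    "update_discrete",
    "update_gaussian",
    "calibrate_prior_moments",
    "linear_gaussian_summary",
]

Structure = Literal["known", "arbitrary", "scaled_identity"]
Coupling = Literal["independent", "homoscedastic"]


def _symmetrize(S: np.ndarray) -> np.ndarray:
    return (S + np.swapaxes(S, -1, -2)) / 2.0


def _is_pd(S: np.ndarray) -> bool:
    S = np.asarray(S, dtype=float)
    tol = 1e-10 * max(float(np.trace(S)), 1e-30)
    try:
        w = np.linalg.eigvalsh(S)
    except np.linalg.LinAlgError:
        return False
    return bool(w.min() > tol)


@dataclass(frozen=True)
class LossMatrix:
    """Loss ``lambda(i, y)`` for predicting ``i`` when the truth is ``y``."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
            raise ValueError(f"loss matrix must be square with M >= 2, got shape {mat.shape}")
        if not np.all(np.isfinite(mat)) or np.any(mat < 0):
            raise ValueError("loss entries must be finite and nonnegative")
        object.__setattr__(self, "matrix", mat)

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    def __call__(self, i: int, y: int) -> float:
        return float(self.matrix[i, y])

    @classmethod
    def zero_one(cls, n_classes: int) -> "LossMatrix":
        return cls(1.0 - np.eye(n_classes))


@dataclass(frozen=True)
class ClassProbPosterior:
    """Posterior knowledge of the class-probability vector ``c``.

    ``known`` holds a fixed point mass ``c``; ``separate_sampling`` keeps a
    Dirichlet prior untouched by the data; ``random_sampling`` is a Dirichlet
    that absorbs the observed class counts additively.
    """

    mode: Literal["known", "separate_sampling", "random_sampling"]
    c: np.ndarray | None = None
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode == "known":
            if self.c is None:
                raise ValueError("known mode requires a class probability vector c")
            c = np.asarray(self.c, dtype=float)
            if c.ndim != 1 or np.any(c < 0) or np.any(c > 1) or abs(c.sum() - 1.0) > 1e-9:
                raise ValueError("known c must lie on the probability simplex")
            object.__setattr__(self, "c", c)
        else:
            if self.alpha is None:
                raise ValueError(f"{self.mode} mode requires Dirichlet parameters alpha")
            a = np.asarray(self.alpha, dtype=float)
            if a.ndim != 1 or np.any(a <= 0):
                raise ValueError("Dirichlet parameters must all be positive")
            object.__setattr__(self, "alpha", a)

    @property
    def n_classes(self) -> int:
        vec = self.c if self.mode == "known" else self.alpha
        return int(vec.shape[0])

    def mean(self) -> np.ndarray:
        """Posterior mean E[C_y | S] = f(y | S)."""
        if self.mode == "known":
            return self.c.copy()
        return self.alpha / self.alpha.sum()


def update_class_prob(prior: ClassProbPosterior, counts: Sequence[int]) -> ClassProbPosterior:
    """Update the class-probability posterior with observed class counts.

    Known and separate-sampling modes are unchanged by the data; under
    random sampling the Dirichlet parameters absorb the counts.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    if prior.mode != "random_sampling":
        return prior
    if counts.shape != prior.alpha.shape:
        raise ValueError("counts length must match the number of classes")
    return replace(prior, alpha=prior.alpha + counts)


def class_prob_moments(post: ClassProbPosterior) -> tuple[np.ndarray, np.ndarray]:
    """First moment ``E[C_y]`` and full second-moment matrix ``E[C_y C_z]``."""
    if post.mode == "known":
        c = post.c
        return c.copy(), np.outer(c, c)
    a = post.alpha
    a_plus = a.sum()
    first = a / a_plus
    second = np.outer(a, a) / (a_plus * (1.0 + a_plus))
    # The diagonal picks up the extra Dirichlet self-correlation term.
    np.fill_diagonal(second, a * (1.0 + a) / (a_plus * (1.0 + a_plus)))
    return first, second


@dataclass(frozen=True)
class DiscretePosterior:
    """Per-class Dirichlet posteriors over ``b`` bins (labels ``1..b``)."""

    alpha: np.ndarray  # shape (M, b)

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 2:
            raise ValueError("alpha must have shape (n_classes, n_bins)")
        if np.any(a <= 0):
            raise ValueError("posterior Dirichlet parameters must all be positive")
        object.__setattr__(self, "alpha", a)

    @property
    def n_classes(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_bins(self) -> int:
        return self.alpha.shape[1]


def update_discrete(prior_alpha: np.ndarray, counts: np.ndarray) -> DiscretePosterior:
    """Dirichlet-multinomial update ``alpha* = alpha + U`` per class and bin."""
    prior_alpha = np.asarray(prior_alpha, dtype=float)
    counts = np.asarray(counts)
    if counts.shape != prior_alpha.shape:
        raise ValueError("counts must match the shape of the prior parameters")
    if np.any(counts < 0):
        raise ValueError("bin counts must be nonnegative")
    post = prior_alpha + counts
    if np.any(post <= 0):
        raise ValueError("posterior Dirichlet parameters must all be positive")
    return DiscretePosterior(post)


@dataclass(frozen=True)
class GaussianPosterior:
    """Hyperparameters of the Gaussian models, prior or posterior.

    ``nu`` and ``m`` parameterize the conditional normal prior on each mean;
    the covariance block is either a fixed ``sigma`` per class (``known``
    structure) or inverse-Wishart-type ``kappa``/``S`` — one per class under
    independent coupling, a single shared pair under homoscedastic coupling.
    ``n`` records the per-class sample sizes absorbed so far.
    """

    structure: Structure
    coupling: Coupling
    nu: np.ndarray  # (M,)
    m: np.ndarray  # (M, D)
    sigma: np.ndarray | None = None  # (M, D, D) for known structure
    kappa: np.ndarray | float | None = None  # (M,) or scalar (homoscedastic)
    S: np.ndarray | None = None  # (M, D, D) or (D, D)
    n: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        m = np.atleast_2d(np.asarray(self.m, dtype=float))
        if m.shape[0] != nu.shape[0]:
            raise ValueError("nu and m must agree on the number of classes")
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "m", m)
        if self.structure == "known":
            if self.sigma is None:
                raise ValueError("known structure requires per-class covariances")
            sig = np.asarray(self.sigma, dtype=float)
            if sig.ndim == 2:
                sig = np.broadcast_to(sig, (self.n_classes,) + sig.shape).copy()
            object.__setattr__(self, "sigma", sig)
        else:
            if self.kappa is None or self.S is None:
                raise ValueError(f"{self.structure} structure requires kappa and S")
            S = np.asarray(self.S, dtype=float)
            if self.coupling == "homoscedastic":
                kappa = float(np.asarray(self.kappa).reshape(()))
                if S.ndim != 2:
                    raise ValueError("homoscedastic coupling stores exactly one S matrix")
            else:
                kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
                if kappa.shape[0] == 1 and self.n_classes > 1:
                    kappa = np.repeat(kappa, self.n_classes)
                if S.ndim == 2:
                    S = np.broadcast_to(S, (self.n_classes,) + S.shape).copy()
                if kappa.shape[0] != self.n_classes or S.shape[0] != self.n_classes:
                    raise ValueError("independent coupling requires kappa and S per class")
            object.__setattr__(self, "kappa", kappa)
            object.__setattr__(self, "S", _symmetrize(S))
        n = self.n
        if n is None:
            n = np.zeros(self.n_classes, dtype=int)
        object.__setattr__(self, "n", np.asarray(n, dtype=int))

    @property
    def n_classes(self) -> int:
        return self.m.shape[0]

    @property
    def dim(self) -> int:
        return self.m.shape[1]

    def kappa_of(self, y: int) -> float:
        return float(self.kappa if self.coupling == "homoscedastic" else self.kappa[y])

    def S_of(self, y: int) -> np.ndarray:
        return self.S if self.coupling == "homoscedastic" else self.S[y]

    def check_proper(self) -> None:
        """Raise ``ValueError`` unless the posterior is proper."""
        D = self.dim
        if np.any(self.nu <= 0):
            raise ValueError(f"improper posterior: all nu must be positive, got {self.nu}")
        if self.structure == "known":
            for y in range(self.n_classes):
                if not _is_pd(self.sigma[y]):
                    raise ValueError(f"covariance of class {y} is not positive definite")
            return
        kappas = [self.kappa] if self.coupling == "homoscedastic" else list(self.kappa)
        Ss = [self.S] if self.coupling == "homoscedastic" else list(self.S)
        for kap, S in zip(kappas, Ss):
            if self.structure == "arbitrary":
                if kap <= D - 1:
                    raise ValueError(f"improper posterior: kappa={kap} must exceed D-1={D - 1}")
            else:
                if (kap + D + 1) * D <= 2:
                    raise ValueError(
                        f"improper posterior: (kappa+D+1)*D={((kap + D + 1) * D)} must exceed 2"
                    )
            if not _is_pd(S):
                raise ValueError("improper posterior: S is not positive definite")


def _class_stats(X: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    n = X.shape[0]
    if n == 0:
        return 0, None, None
    mean = X.mean(axis=0)
    if n <= 1:
        cov = np.zeros((X.shape[1], X.shape[1]))
    else:
        cov = np.cov(X, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
    return n, mean, cov


def update_gaussian(prior: GaussianPosterior, X: np.ndarray, labels: np.ndarray) -> GaussianPosterior:
    """Absorb a labeled sample into the conjugate Gaussian posterior.

    Mean hyperparameters update as ``nu* = nu + n_y`` and
    ``m* = m + n_y (mu_hat - m) / (nu + n_y)``.  Covariance hyperparameters
    update per class (independent coupling) or jointly (homoscedastic) with
    the scatter term ``(n_y - 1) Sigma_hat + nu n_y / (nu + n_y)
    (mu_hat - m)(mu_hat - m)^T``; the sample covariance is taken as zero for
    ``n_y <= 1``.  Known covariances are left untouched.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != prior.dim:
        raise ValueError(f"data must have shape (n, {prior.dim})")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels must align with data rows")
    M, D = prior.n_classes, prior.dim

    nu = prior.nu.copy()
    m = prior.m.copy()
    n_new = prior.n.copy()
    scatter = np.zeros((M, D, D))
    counts = np.zeros(M, dtype=int)
    for y in range(M):
        ny, mu_hat, cov_hat = _class_stats(X[labels == y])
        counts[y] = ny
        n_new[y] += ny
        if ny == 0:
            continue
        diff = mu_hat - prior.m[y]
        scatter[y] = (ny - 1) * cov_hat + (prior.nu[y] * ny / (prior.nu[y] + ny)) * np.outer(diff, diff)
        nu[y] = prior.nu[y] + ny
        m[y] = prior.m[y] + ny * diff / (prior.nu[y] + ny)

    if prior.structure == "known":
        return replace(prior, nu=nu, m=m, n=n_new)
    if prior.coupling == "homoscedastic":
        kappa = prior.kappa + counts.sum()
        S = _symmetrize(prior.S + scatter.sum(axis=0))
    else:
        kappa = prior.kappa + counts
        S = _symmetrize(prior.S + scatter)
    return replace(prior, nu=nu, m=m, kappa=kappa, S=S, n=n_new)


def _trimmed_variance(values: np.ndarray, key: np.ndarray) -> float:
    """Sample variance after discarding the ceil(10%) entries largest by key."""
    order = np.argsort(key, kind="stable")
    n_drop = math.ceil(0.1 * values.shape[0])
    kept = values[order[: values.shape[0] - n_drop]]
    if kept.shape[0] < 2:
        raise ValueError("too few calibration features remain after trimming")
    return float(np.var(kept, ddof=1))


def calibrate_prior_moments(
    features: np.ndarray, labels: np.ndarray, dim: int
) -> GaussianPosterior:
    """Method-of-moments prior calibration from held-out calibration features.

    For each class ``y``, with per-feature means and variances across the
    class-``y`` calibration rows: ``m_y`` is the mean of the means, ``s_y``
    the mean of the variances, ``t_y`` the variance of the means after
    discarding the 10 % with the largest absolute value, and ``u_y`` the
    variance of the variances after discarding the largest 10 %.  Then
    ``nu_y = s_y / t_y``, ``kappa_y = 2 s_y^2 / u_y + D + 3``, the location
    is the constant vector ``m_y`` and ``S_y = (kappa_y - D - 1) s_y I_D``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    M = classes.shape[0]
    nu = np.empty(M)
    kappa = np.empty(M)
    m = np.empty((M, dim))
    S = np.empty((M, dim, dim))
    for idx, y in enumerate(classes):
        block = features[labels == y]
        if block.shape[0] < 2 or block.shape[1] < 2:
            raise ValueError("need at least 2 calibration rows and features per class")
        means = block.mean(axis=0)
        variances = block.var(axis=0, ddof=1)
        m_y = float(means.mean())
        s_y = float(variances.mean())
        t_y = _trimmed_variance(means, np.abs(means))
        u_y = _trimmed_variance(variances, variances)
        if t_y == 0 or u_y == 0:
            raise ValueError(f"degenerate calibration data for class {y}: zero trimmed variance")
        nu[idx] = s_y / t_y
        kappa[idx] = 2.0 * (s_y**2 / u_y) + dim + 3
        m[idx] = m_y
        S[idx] = (kappa[idx] - dim - 1) * s_y * np.eye(dim)
    return GaussianPosterior(
        structure="arbitrary", coupling="independent", nu=nu, m=m, kappa=kappa, S=S
    )


@dataclass(frozen=True)
class LinearGaussianSummary:
    """Scalars reducing a binary linear classifier under a Gaussian posterior
    to one dimension: signed discriminant offset ``m_iy = (-1)^i g(m*_y)``,
    squared scale ``gamma2``, effective degrees of freedom ``k`` (``inf``
    marks the known-covariance normal case) and ``nu*_y``.
    """

    m_iy: float
    gamma2: float
    k: float
    nu_star: float


def linear_gaussian_summary(
    post: GaussianPosterior, y: int, a: np.ndarray, b: float, i: int
) -> LinearGaussianSummary:
    """Summaries of ``(-1)^i (a^T X + b)`` for a class-``y`` point under the
    posterior; the model structure fixes ``gamma2`` and the degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    D = post.dim
    m_iy = float((-1.0) ** i * (a @ post.m[y] + b))
    if post.structure == "known":
        gamma2 = float(a @ post.sigma[y] @ a)
        k = math.inf
    elif post.structure == "arbitrary":
        gamma2 = float(a @ post.S_of(y) @ a)
        k = post.kappa_of(y) - D + 1
    else:  # scaled identity
        gamma2 = float(np.trace(post.S_of(y)) * (a @ a))
        k = (post.kappa_of(y) + D + 1) * D - 2
    if gamma2 <= 0:
        raise ValueError("degenerate linear classifier: a must not be null under S")
    return LinearGaussianSummary(m_iy=m_iy, gamma2=gamma2, k=k, nu_star=float(post.nu[y]))
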