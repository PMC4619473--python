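"""Effective (posterior-predictive) densities, their conditionals, joints
over point pairs, and exact samplers.

The effective class-``y`` density is the posterior expectation of the
class-conditional density and plays the role of the true density in the
Bayesian risk expressions: categorical for the discrete model, Gaussian for
known covariances, multivariate Student t otherwise.  The effective joint
density of two points (x, w) is what the second moments of misclassification
probabilities integrate over; within one covariance-coupling group it is a
single elliptical law (one shared degrees-of-freedom mixing variable), not a
product of two t distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .models import DiscretePosterior, GaussianPosterior, update_discrete, update_gaussian

__all__ = [
    "Categorical",
    "Gaussian",
    "StudentT",
    "CategoricalJoint",
    "ProductDensity",
    "effective_density",
    "effective_conditional",
    "effective_joint",
    "sample_effective",
    "sample_conditional",
    "ConditionalJoint",
    "marginal",
]


@dataclass(frozen=True)
class Categorical:
    """Probability vector over bins ``1..b``."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("categorical probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        idx = np.asarray(x, dtype=int) - 1
        with np.errstate(divide="ignore"):
            return np.log(self.probs)[idx]

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.probs.shape[0], size=n, p=self.probs) + 1


@dataclass(frozen=True)
class Gaussian:
    mean_vec: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_vec", np.atleast_1d(np.asarray(self.mean_vec, float)))
        object.__setattr__(self, "cov", np.atleast_2d(np.asarray(self.cov, float)))

    @property
    def dim(self) -> int:
        return self.mean_vec.shape[0]

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return stats.multivariate_normal.logpdf(x, mean=self.mean_vec, cov=self.cov)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mean_vec, self.cov, size=n, method="cholesky")

    def mean(self) -> np.ndarray:
        return self.mean_vec.copy()

    def covariance(self) -> np.ndarray:
        return self.cov.copy()


@dataclass(frozen=True)
class StudentT:
    """Multivariate Student t with ``df`` degrees of freedom, location and
    scale matrix (density ``(1 + (x-mu)' Lam^-1 (x-mu)/df)^(-(df+D)/2)``)."""

    df: float
    loc: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        object.__setattr__(self, "loc", np.atleast_1d(np.asarray(self.loc, float)))
        object.__setattr__(self, "scale", np.atleast_2d(np.asarray(self.scale, float)))

    @property
    def dim(self) -> int:
        return self.loc.shape[0]

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return stats.multivariate_t.logpdf(x, loc=self.loc, shape=self.scale, df=self.df)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # One chi-square mixing variable per draw: the whole vector (including
        # any stacked (x, w) block) is a single elliptical draw.
        z = rng.multivariate_normal(np.zeros(self.dim), self.scale, size=n, method="cholesky")
        u = rng.chisquare(self.df, size=n)
        return self.loc + z * np.sqrt(self.df / u)[:, None]

    def mean(self) -> np.ndarray:
        if self.df <= 1:
            raise ValueError("mean undefined for df <= 1")
        return self.loc.copy()

    def covariance(self) -> np.ndarray:
        if self.df <= 2:
            raise ValueError("covariance undefined for df <= 2")
        return self.df / (self.df - 2.0) * self.scale


@dataclass(frozen=True)
class CategoricalJoint:
    """Joint pmf over bin pairs; entry [x-1, w-1] is P(x, w)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("joint pmf entries must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    def marginals(self) -> tuple[Categorical, Categorical]:
        return Categorical(self.probs.sum(axis=1)), Categorical(self.probs.sum(axis=0))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        b = self.probs.shape[0]
        flat = rng.choice(b * b, size=n, p=self.probs.ravel())
        return np.stack([flat // b + 1, flat % b + 1], axis=1)


@dataclass(frozen=True)
class ProductDensity:
    """Joint law of two independent blocks, used when the two classes'
    parameters are a priori independent (the joint then factorizes)."""

    first: object
    second: object

    def logpdf(self, xw: np.ndarray) -> np.ndarray:
        xw = np.atleast_2d(xw)
        d = self.first.dim
        return self.first.logpdf(xw[:, :d]) + self.second.logpdf(xw[:, d:])

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.concatenate([self.first.rvs(n, rng), self.second.rvs(n, rng)], axis=1)

    def marginals(self) -> tuple[object, object]:
        return self.first, self.second


def _gaussian_dof_scale(post: GaussianPosterior, y: int) -> tuple[float, np.ndarray]:
    """Effective-density degrees of freedom and scale-shape matrix for class y.

    Returns (k, A) such that the effective density is t(k, m*_y,
    (nu*+1)/(k nu*) A): A = S* for arbitrary structure and trace(S*) I for
    scaled identity.
    """
    D = post.dim
    if post.structure == "arbitrary":
        k = post.kappa_of(y) - D + 1
        A = post.S_of(y)
    else:
        k = (post.kappa_of(y) + D + 1) * D - 2
        A = np.trace(post.S_of(y)) * np.eye(D)
    return float(k), A


def effective_density(post, y: int):
    """Effective class-``y`` conditional density under the posterior."""
    if isinstance(post, DiscretePosterior):
        a = post.alpha[y]
        return Categorical(a / a.sum())
    post.check_proper()
    nu = float(post.nu[y])
    if post.structure == "known":
        return Gaussian(post.m[y], (nu + 1.0) / nu * post.sigma[y])
    k, A = _gaussian_dof_scale(post, y)
    if k <= 0:
        raise ValueError(f"effective density has nonpositive degrees of freedom k={k}")
    return StudentT(df=k, loc=post.m[y], scale=(nu + 1.0) / (k * nu) * A)


def _rank_one_scatter(post: GaussianPosterior, x: np.ndarray, y: int) -> np.ndarray:
    diff = np.asarray(x, float) - post.m[y]
    return post.nu[y] / (post.nu[y] + 1.0) * np.outer(diff, diff)


def _covariance_only_update(post: GaussianPosterior, x: np.ndarray, y: int) -> GaussianPosterior:
    """Update only (kappa*, S*) with the point {x, y}; used for the effective
    conditional density of a class-z point given a class-y point, z != y,
    under homoscedastic coupling."""
    return replace(post, kappa=post.kappa + 1.0, S=post.S + _rank_one_scatter(post, x, y))


def effective_conditional(post, x, y: int, z: int):
    """Effective density of a class-``z`` point given an observed point
    ``{x, y}``: the posterior absorbs the extra point — fully for ``z = y``,
    covariance hyperparameters only for ``z != y`` under homoscedastic
    coupling, and not at all otherwise (posterior independence).
    """
    if isinstance(post, DiscretePosterior):
        if z != y:
            return effective_density(post, z)
        counts = np.zeros_like(post.alpha)
        counts[y, int(x) - 1] = 1
        return effective_density(update_discrete(post.alpha, counts), z)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape[0] != post.dim:
        raise ValueError(f"point has dimension {x.shape[0]}, expected {post.dim}")
    if z == y:
        updated = update_gaussian(post, x[None, :], np.array([y]))
        return effective_density(updated, z)
    if post.structure == "known" or post.coupling == "independent":
        return effective_density(post, z)
    return effective_density(_covariance_only_update(post, x, y), z)


def _block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Symmetric 2x2 block matrix [[A, B], [B, A']] with equal diagonals."""
    top = np.concatenate([A, B], axis=1)
    bottom = np.concatenate([B, A], axis=1)
    return np.concatenate([top, bottom], axis=0)


def sample_conditional(post, xs: np.ndarray, y: int, z: int, rng: np.random.Generator) -> np.ndarray:
    """One draw from the effective conditional density f(w | x, y, z, S) for
    each point in ``xs``, vectorized over points.

    For Gaussian models the x-dependent scale matrix is a rank-one update of
    the base scatter, so a conditional draw is ``L z1 + sqrt(r) d z2`` with a
    shared Cholesky factor — no per-point decompositions.
    """
    if isinstance(post, DiscretePosterior):
        xs = np.asarray(xs, dtype=int)
        a = post.alpha[z].astype(float)
        a_plus = a.sum()
        n = xs.shape[0]
        base = rng.choice(a.shape[0], size=n, p=a / a_plus) + 1
        if z != y:
            return base
        take_x = rng.random(n) < 1.0 / (a_plus + 1.0)
        return np.where(take_x, xs, base)
    xs = np.atleast_2d(np.asarray(xs, float))
    n, D = xs.shape
    nu_y, nu_z = float(post.nu[y]), float(post.nu[z])
    diff = xs - post.m[y]
    if post.structure == "known":
        if z != y:
            return effective_density(post, z).rvs(n, rng)
        loc = post.m[y] + diff / (nu_y + 1.0)
        cov = (nu_y + 2.0) / (nu_y + 1.0) * post.sigma[y]
        return loc + rng.multivariate_normal(np.zeros(D), cov, size=n, method="cholesky")
    if z != y and post.coupling == "independent":
        return effective_density(post, z).rvs(n, rng)
    # Student-t conditionals: dof k_c, location, scale c * (A + r d d').
    r = nu_y / (nu_y + 1.0)
    S = post.S_of(y)
    if post.structure == "arbitrary":
        k_c = post.kappa_of(y) - D + 2
        base = S
        scalar_scale = False
    else:
        k_c = (post.kappa_of(y) + D + 1) * D - 2 + D
        base = np.trace(S) * np.eye(D)
        scalar_scale = True
    if z == y:
        loc = post.m[y] + diff / (nu_y + 1.0)
        c = (nu_y + 2.0) / (k_c * (nu_y + 1.0))
    else:  # homoscedastic, z != y
        loc = np.broadcast_to(post.m[z], (n, D))
        c = (nu_z + 1.0) / (k_c * nu_z)
    u = rng.chisquare(k_c, size=n)
    t_mix = np.sqrt(k_c / u)[:, None]
    z1 = rng.standard_normal((n, D))
    if scalar_scale:
        s2 = c * (np.trace(S) + r * np.einsum("nd,nd->n", diff, diff))
        return loc + np.sqrt(s2)[:, None] * z1 * t_mix
    L = np.linalg.cholesky(c * base)
    z2 = rng.standard_normal(n)[:, None]
    return loc + (z1 @ L.T + np.sqrt(c * r) * diff * z2) * t_mix


@dataclass(frozen=True)
class ConditionalJoint:
    """Exact joint law of (X, W) composed as marginal times conditional.

    Under the arbitrary-covariance models in dimension D > 1 the stacked
    pair is matrix-variate t rather than multivariate t (the conditional
    scale is a rank-one — not isotropic — update), so the joint is kept in
    product form: the density is ``f(x | y, S) f(w | x, y, z, S)`` and
    sampling draws W from the effective conditional given each X.
    """

    post: object
    y: int
    z: int

    def marginals(self) -> tuple[object, object]:
        return effective_density(self.post, self.y), effective_density(self.post, self.z)

    def logpdf(self, xw: np.ndarray) -> np.ndarray:
        xw = np.atleast_2d(xw)
        d = self.post.dim
        fx = effective_density(self.post, self.y)
        out = np.empty(xw.shape[0])
        for idx in range(xw.shape[0]):
            x, w = xw[idx, :d], xw[idx, d:]
            cond = effective_conditional(self.post, x, self.y, self.z)
            out[idx] = np.squeeze(fx.logpdf(x)) + np.squeeze(cond.logpdf(w))
        return out

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        xs = effective_density(self.post, self.y).rvs(n, rng)
        ws = sample_conditional(self.post, xs, self.y, self.z, rng)
        return np.concatenate([xs, ws], axis=1)


def effective_joint(post, y: int, z: int):
    """Effective joint density of a class-``y`` point X and class-``z``
    point W (stacked as a 2D-dimensional vector for the Gaussian models)."""
    if isinstance(post, DiscretePosterior):
        if y == z:
            a = post.alpha[y]
            a_plus = a.sum()
            mat = np.outer(a, a) + np.diag(a)
            return CategoricalJoint(mat / (a_plus * (a_plus + 1.0)))
        py = post.alpha[y] / post.alpha[y].sum()
        pz = post.alpha[z] / post.alpha[z].sum()
        return CategoricalJoint(np.outer(py, pz))
    post.check_proper()
    D = post.dim
    nu_y, nu_z = float(post.nu[y]), float(post.nu[z])
    if post.structure == "known":
        if y == z:
            cov = _block((nu_y + 1.0) / nu_y * post.sigma[y], post.sigma[y] / nu_y)
            return Gaussian(np.concatenate([post.m[y], post.m[y]]), cov)
        return ProductDensity(effective_density(post, y), effective_density(post, z))
    if post.structure == "arbitrary" and D > 1:
        # Stacked pair is matrix-variate t; keep the exact product form.
        if y != z and post.coupling == "independent":
            return ProductDensity(effective_density(post, y), effective_density(post, z))
        return ConditionalJoint(post, y, z)
    if y == z:
        k, A = _gaussian_dof_scale(post, y)
        scale = _block((nu_y + 1.0) / nu_y * A, A / nu_y) / k
        return StudentT(df=k, loc=np.concatenate([post.m[y], post.m[y]]), scale=scale)
    if post.coupling == "independent":
        return ProductDensity(effective_density(post, y), effective_density(post, z))
    # Homoscedastic, y != z: block-diagonal scale but one shared dof.
    k, A = _gaussian_dof_scale(post, y)
    scale = np.zeros((2 * D, 2 * D))
    scale[:D, :D] = (nu_y + 1.0) / nu_y * A / k
    scale[D:, D:] = (nu_z + 1.0) / nu_z * A / k
    return StudentT(df=k, loc=np.concatenate([post.m[y], post.m[z]]), scale=scale)


def sample_effective(density, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. points from an effective (joint) density."""
    if n < 1:
        raise ValueError("sample size must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return density.rvs(n, rng)


def marginal(joint, which: int):
    """Extract one D-dimensional marginal of a stacked joint density."""
    if hasattr(joint, "marginals"):
        return joint.marginals()[which]
    dim = joint.dim // 2
    sl = slice(0, dim) if which == 0 else slice(dim, 2 * dim)
    if isinstance(joint, Gaussian):
        return Gaussian(joint.mean_vec[sl], joint.cov[sl, sl])
    return StudentT(joint.df, joint.loc[sl], joint.scale[sl, sl])
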