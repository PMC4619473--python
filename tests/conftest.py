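import numpy as np
import pytest

from obrc.models import DiscretePosterior, GaussianPosterior, update_gaussian

ALL_GAUSSIAN_VARIANTS = [
    ("known", "independent"),
    ("arbitrary", "independent"),
    ("arbitrary", "homoscedastic"),
    ("scaled_identity", "independent"),
    ("scaled_identity", "homoscedastic"),
]


def make_prior(structure: str, coupling: str, D: int = 2, M: int = 2) -> GaussianPosterior:
    """Proper two-class prior of the requested covariance variant."""
    nu = np.arange(1.0, M + 1.0)
    m = np.linspace(-0.5, 0.5, M)[:, None] * np.ones(D)
    if structure == "known":
        sigma = np.stack([(1.0 + 0.5 * y) * np.eye(D) for y in range(M)])
        return GaussianPosterior("known", "independent", nu=nu, m=m, sigma=sigma)
    if coupling == "homoscedastic":
        return GaussianPosterior(structure, coupling, nu=nu, m=m, kappa=6.0, S=0.9 * np.eye(D))
    kappa = 6.0 + np.arange(M)
    S = np.stack([(0.9 + 0.3 * y) * np.eye(D) for y in range(M)])
    return GaussianPosterior(structure, coupling, nu=nu, m=m, kappa=kappa, S=S)


def make_posterior(structure: str, coupling: str, D: int = 2, M: int = 2,
                   n_per_class: int = 6, seed: int = 42) -> GaussianPosterior:
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_per_class * M, D))
    labels = np.repeat(np.arange(M), n_per_class)
    return update_gaussian(make_prior(structure, coupling, D, M), X, labels)


@pytest.fixture
def discrete_toy() -> DiscretePosterior:
    """Two classes over two bins: alpha0* = (4, 2), alpha1* = (2, 4)."""
    return DiscretePosterior(np.array([[4.0, 2.0], [2.0, 4.0]]))
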