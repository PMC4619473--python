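"""Effective densities, conditionals, joints, and their exact samplers."""

import numpy as np
import pytest

from obrc.densities import (
    Categorical,
    CategoricalJoint,
    ConditionalJoint,
    Gaussian,
    ProductDensity,
    StudentT,
    effective_conditional,
    effective_density,
    effective_joint,
    marginal,
    sample_conditional,
    sample_effective,
)
from obrc.models import DiscretePosterior, GaussianPosterior, update_gaussian
from tests.conftest import ALL_GAUSSIAN_VARIANTS, make_posterior


def _lp(density, point) -> float:
    return float(np.squeeze(density.logpdf(point)))


class TestEffectiveDensity:
    def test_discrete_posterior_mean_probs(self, discrete_toy):
        d = effective_density(discrete_toy, 0)
        np.testing.assert_allclose(d.probs, [2 / 3, 1 / 3])

    def test_known_covariance_inflation(self):
        post = GaussianPosterior("known", "independent", nu=[1.0, 1.0],
                                 m=np.zeros((2, 2)),
                                 sigma=np.stack([np.eye(2)] * 2))
        d = effective_density(post, 0)
        assert isinstance(d, Gaussian)
        np.testing.assert_allclose(d.cov, 2.0 * np.eye(2))

    def test_arbitrary_dof(self):
        post = make_posterior("arbitrary", "homoscedastic")
        d = effective_density(post, 0)
        # k = kappa* - D + 1 with kappa* = 6 + n
        assert d.df == pytest.approx(post.kappa - 2 + 1)
        np.testing.assert_allclose(
            d.scale, (post.nu[0] + 1) / (d.df * post.nu[0]) * post.S, atol=1e-12
        )

    def test_scaled_identity_dof_and_isotropic_scale(self):
        post = make_posterior("scaled_identity", "independent")
        d = effective_density(post, 1)
        k = (post.kappa[1] + 2 + 1) * 2 - 2
        assert d.df == pytest.approx(k)
        expected = (post.nu[1] + 1) / (k * post.nu[1]) * np.trace(post.S[1]) * np.eye(2)
        np.testing.assert_allclose(d.scale, expected, atol=1e-12)

    def test_improper_posterior_rejected(self):
        post = GaussianPosterior("arbitrary", "independent", nu=[0.0, 1.0],
                                 m=np.zeros((2, 2)), kappa=[6.0, 6.0],
                                 S=np.stack([np.eye(2)] * 2))
        with pytest.raises(ValueError):
            effective_density(post, 0)


class TestEffectiveConditional:
    def test_known_covariance_single_point(self):
        post = GaussianPosterior("known", "independent", nu=[1.0, 1.0],
                                 m=np.zeros((2, 1)), sigma=np.ones((2, 1, 1)))
        cond = effective_conditional(post, np.array([1.0]), 0, 0)
        assert cond.mean_vec[0] == pytest.approx(0.5)  # m* + (x - m*)/(nu*+1)
        assert cond.cov[0, 0] == pytest.approx(1.5)  # (nu*+2)/(nu*+1) Sigma

    @pytest.mark.parametrize("structure, coupling", ALL_GAUSSIAN_VARIANTS)
    def test_same_class_matches_single_point_posterior_update(self, structure, coupling):
        post = make_posterior(structure, coupling)
        x = np.array([0.4, -0.2])
        cond = effective_conditional(post, x, 1, 1)
        updated = update_gaussian(post, x[None, :], np.array([1]))
        expected = effective_density(updated, 1)
        assert type(cond) is type(expected)
        if isinstance(cond, Gaussian):
            np.testing.assert_allclose(cond.mean_vec, expected.mean_vec, atol=1e-12)
            np.testing.assert_allclose(cond.cov, expected.cov, atol=1e-12)
        else:
            assert cond.df == pytest.approx(expected.df)
            np.testing.assert_allclose(cond.loc, expected.loc, atol=1e-12)
            np.testing.assert_allclose(cond.scale, expected.scale, atol=1e-12)

    @pytest.mark.parametrize("structure", ["known", "arbitrary", "scaled_identity"])
    def test_other_class_independent_coupling_unchanged(self, structure):
        post = make_posterior(structure, "independent")
        x = np.array([1.0, 1.0])
        cond = effective_conditional(post, x, 0, 1)
        base = effective_density(post, 1)
        pts = np.array([[0.0, 0.0], [1.2, -0.3]])
        np.testing.assert_allclose(cond.logpdf(pts), base.logpdf(pts), atol=1e-12)

    @pytest.mark.parametrize("structure", ["arbitrary", "scaled_identity"])
    def test_homoscedastic_cross_class_covariance_only_update(self, structure):
        post = make_posterior(structure, "homoscedastic")
        x = np.array([0.8, -0.6])
        cond = effective_conditional(post, x, 0, 1)
        # Location of class z is untouched; dof and scale absorb the scatter.
        np.testing.assert_allclose(cond.loc, post.m[1], atol=1e-12)
        diff = x - post.m[0]
        S_extra = post.nu[0] / (post.nu[0] + 1) * np.outer(diff, diff)
        if structure == "arbitrary":
            k1 = post.kappa + 1 - 2 + 1
            expected_scale = (post.nu[1] + 1) / (k1 * post.nu[1]) * (post.S + S_extra)
        else:
            k1 = (post.kappa + 1 + 2 + 1) * 2 - 2
            expected_scale = (
                (post.nu[1] + 1) / (k1 * post.nu[1]) * np.trace(post.S + S_extra) * np.eye(2)
            )
        assert cond.df == pytest.approx(k1)
        np.testing.assert_allclose(cond.scale, expected_scale, atol=1e-12)

    def test_discrete_conditional_updates_counts(self, discrete_toy):
        cond = effective_conditional(discrete_toy, 1, 0, 0)
        np.testing.assert_allclose(cond.probs, [5 / 7, 2 / 7])
        unchanged = effective_conditional(discrete_toy, 1, 0, 1)
        np.testing.assert_allclose(unchanged.probs, [1 / 3, 2 / 3])

    def test_dimension_mismatch_rejected(self):
        post = make_posterior("arbitrary", "independent")
        with pytest.raises(ValueError):
            effective_conditional(post, np.array([1.0, 2.0, 3.0]), 0, 0)


class TestEffectiveJoint:
    def test_discrete_same_class_formula(self, discrete_toy):
        joint = effective_joint(discrete_toy, 0, 0)
        # P(x=1, w=1) = 4*5 / (6*7)
        assert joint.probs[0, 0] == pytest.approx(10 / 21)
        assert joint.probs.sum() == pytest.approx(1.0)
        m0, m1 = joint.marginals()
        np.testing.assert_allclose(m0.probs, [2 / 3, 1 / 3])
        np.testing.assert_allclose(m1.probs, [2 / 3, 1 / 3])

    def test_discrete_cross_class_factorizes(self, discrete_toy):
        joint = effective_joint(discrete_toy, 0, 1)
        np.testing.assert_allclose(joint.probs, np.outer([2 / 3, 1 / 3], [1 / 3, 2 / 3]))

    def test_known_covariance_block_structure(self):
        post = make_posterior("known", "independent")
        joint = effective_joint(post, 0, 0)
        nu = post.nu[0]
        np.testing.assert_allclose(joint.cov[:2, 2:], post.sigma[0] / nu, atol=1e-12)
        m = marginal(joint, 1)
        base = effective_density(post, 0)
        np.testing.assert_allclose(m.cov, base.cov, atol=1e-12)

    @pytest.mark.parametrize("structure", ["arbitrary", "scaled_identity"])
    def test_independent_cross_class_is_product(self, structure):
        post = make_posterior(structure, "independent")
        joint = effective_joint(post, 0, 1)
        assert isinstance(joint, ProductDensity)
        xw = np.array([[0.1, 0.2, -0.3, 0.4]])
        expected = effective_density(post, 0).logpdf(xw[:, :2]) + effective_density(
            post, 1
        ).logpdf(xw[:, 2:])
        np.testing.assert_allclose(joint.logpdf(xw), expected, atol=1e-12)

    @pytest.mark.parametrize(
        "structure, coupling, y, z",
        [
            ("scaled_identity", "homoscedastic", 0, 0),  # I = 1 branch
            ("scaled_identity", "homoscedastic", 0, 1),  # I = 0 branch
            ("scaled_identity", "independent", 1, 1),
            ("arbitrary", "homoscedastic", 0, 0),
            ("arbitrary", "homoscedastic", 1, 0),
            ("arbitrary", "independent", 0, 0),
        ],
    )
    def test_joint_equals_marginal_times_conditional(self, structure, coupling, y, z):
        """The defining identity f(x,w|y,z,S) = f(x|y,S) f(w|x,y,z,S)."""
        post = make_posterior(structure, coupling)
        joint = effective_joint(post, y, z)
        rng = np.random.default_rng(9)
        for _ in range(25):
            x, w = rng.normal(size=2), rng.normal(size=2)
            lhs = np.exp(_lp(joint, np.concatenate([x, w])))
            rhs = np.exp(
                _lp(effective_density(post, y), x)
                + _lp(effective_conditional(post, x, y, z), w)
            )
            assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_one_dimensional_arbitrary_joint_is_bivariate_t(self):
        post = make_posterior("arbitrary", "homoscedastic", D=1)
        joint = effective_joint(post, 0, 0)
        assert isinstance(joint, StudentT)
        nu = post.nu[0]
        k = post.kappa - 1 + 1
        gamma2 = float(post.S[0, 0])
        expected = gamma2 / k * np.array(
            [[(nu + 1) / nu, 1 / nu], [1 / nu, (nu + 1) / nu]]
        )
        np.testing.assert_allclose(joint.scale, expected, atol=1e-12)

    def test_arbitrary_multidim_joint_is_exact_composition(self):
        post = make_posterior("arbitrary", "independent")
        joint = effective_joint(post, 0, 0)
        assert isinstance(joint, ConditionalJoint)
        m0, _ = joint.marginals()
        base = effective_density(post, 0)
        assert m0.df == base.df


class TestSamplers:
    def test_categorical_frequencies(self):
        rng = np.random.default_rng(0)
        draws = sample_effective(Categorical(np.array([2 / 3, 1 / 3])), 60_000, rng)
        assert np.mean(draws == 1) == pytest.approx(2 / 3, abs=0.01)

    def test_student_t_median_and_covariance(self):
        rng = np.random.default_rng(1)
        d = StudentT(df=5.0, loc=np.array([0.0]), scale=np.array([[1.0]]))
        draws = sample_effective(d, 100_000, rng)
        assert np.median(draws) == pytest.approx(0.0, abs=0.02)
        # Var = df/(df-2) * scale
        assert draws.var() == pytest.approx(5 / 3, rel=0.05)

    def test_joint_t_correlation_structure(self):
        # Within-pair correlation of (P, Q) follows the printed block scale:
        # off-diagonal 1/nu* against diagonal (nu*+1)/nu*.
        rng = np.random.default_rng(2)
        nu, k = 3.0, 6.0
        scale = np.array([[(nu + 1) / nu, 1 / nu], [1 / nu, (nu + 1) / nu]]) / k
        d = StudentT(df=k, loc=np.zeros(2), scale=scale)
        draws = sample_effective(d, 200_000, rng)
        corr = np.corrcoef(draws.T)[0, 1]
        assert corr == pytest.approx(1 / (nu + 1), abs=0.02)

    @pytest.mark.parametrize("structure, coupling", ALL_GAUSSIAN_VARIANTS)
    def test_effective_density_sample_moments(self, structure, coupling):
        post = make_posterior(structure, coupling)
        d = effective_density(post, 0)
        rng = np.random.default_rng(3)
        draws = sample_effective(d, 120_000, rng)
        np.testing.assert_allclose(draws.mean(axis=0), d.mean(), atol=0.03)
        np.testing.assert_allclose(
            np.cov(draws, rowvar=False), d.covariance(), atol=0.12 * np.abs(d.covariance()).max()
        )

    def test_conditional_sampler_matches_conditional_density_moments(self):
        # Vectorized rank-one sampler against the analytic conditional law.
        post = make_posterior("arbitrary", "homoscedastic")
        x = np.array([0.7, -0.4])
        rng = np.random.default_rng(4)
        ws = sample_conditional(post, np.tile(x, (150_000, 1)), 0, 0, rng)
        cond = effective_conditional(post, x, 0, 0)
        np.testing.assert_allclose(ws.mean(axis=0), cond.loc, atol=0.02)
        np.testing.assert_allclose(
            np.cov(ws, rowvar=False), cond.df / (cond.df - 2) * cond.scale, rtol=0.08
        )

    def test_reproducible_given_seed(self):
        d = StudentT(df=4.0, loc=np.zeros(2), scale=np.eye(2))
        a = sample_effective(d, 100, seed=7)
        b = sample_effective(d, 100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_sample_size_validated(self):
        with pytest.raises(ValueError):
            sample_effective(Categorical(np.array([1.0])), 0)
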