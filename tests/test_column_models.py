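"""Closed-form conjugate column models: predictives, marginals,
incremental updates, and their exchangeability/chain-rule structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats
from scipy.special import logsumexp

from madmix.column_models import CategoricalModel, GaussianModel


def cat_with_counts(k, counts, pseudo=1.0):
    m = CategoricalModel(k, pseudo)
    for x, c in enumerate(counts):
        for _ in range(c):
            m.add_row(x)
    return m


class TestCategorical:
    def test_uniform_prior_predictive(self):
        m = CategoricalModel(2)
        assert m.log_predictive(0) == pytest.approx(math.log(0.5))

    def test_predictive_with_counts(self):
        # counts (3,1), c=(1,1): P(x=0) = (3+1)/(4+2)
        m = cat_with_counts(2, [3, 1])
        assert m.log_predictive(0) == pytest.approx(math.log(4 / 6))

    @pytest.mark.parametrize("k,counts", [(2, [3, 1]), (4, [0, 2, 5, 1])])
    def test_predictives_normalize(self, k, counts):
        m = cat_with_counts(k, counts)
        total = sum(math.exp(m.log_predictive(x)) for x in range(k))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_marginal_is_zero(self):
        assert CategoricalModel(3).log_marginal() == pytest.approx(0.0)

    def test_single_observation_marginal(self):
        m = cat_with_counts(2, [1, 0])
        assert m.log_marginal() == pytest.approx(math.log(0.5))

    def test_marginal_equals_chained_predictives_all_orders(self):
        # counts (2,1): every insertion order gives the same marginal
        import itertools

        vals = []
        for order in itertools.permutations([0, 0, 1]):
            m = CategoricalModel(2)
            chained = 0.0
            for x in order:
                chained += m.log_predictive(x)
                m.add_row(x)
            vals.append(chained)
            assert m.log_marginal() == pytest.approx(chained, abs=1e-12)
        assert max(vals) - min(vals) < 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 3), max_size=12))
    def test_chain_rule_identity(self, xs):
        m = CategoricalModel(4, pseudo_counts=0.7)
        chained = 0.0
        for x in xs:
            chained += m.log_predictive(x)
            m.add_row(x)
        assert m.log_marginal() == pytest.approx(chained, abs=1e-8)

    def test_add_remove_restores_counts(self):
        m = cat_with_counts(3, [1, 2, 0])
        before = m.counts.copy()
        m.add_row(2)
        m.remove_row(2)
        np.testing.assert_array_equal(m.counts, before)

    def test_remove_uncounted_value_errors(self):
        m = CategoricalModel(2)
        with pytest.raises(ValueError):
            m.remove_row(0)

    def test_category_out_of_range_errors(self):
        m = CategoricalModel(3)
        with pytest.raises(ValueError):
            m.log_predictive(3)
        with pytest.raises(ValueError):
            m.add_row(-1)

    def test_nonpositive_pseudo_counts_rejected(self):
        with pytest.raises(ValueError):
            CategoricalModel(2, pseudo_counts=0.0)


class TestGaussianPosterior:
    def test_no_data_identity(self):
        m = GaussianModel(mu0=1.5, beta0=2.0, a0=3.0, b0=0.5)
        assert m.posterior() == (1.5, 2.0, 3.0, 0.5)

    def test_single_datum_hand_values(self):
        # mu0=0, beta0=1, x=2: mu_n=1, beta_n=2, a_n=a0+1/2, b_n=b0+1
        m = GaussianModel(mu0=0.0, beta0=1.0, a0=1.3, b0=0.8)
        m.add_row(2.0)
        mu_n, beta_n, a_n, b_n = m.posterior()
        assert mu_n == pytest.approx(1.0)
        assert beta_n == pytest.approx(2.0)
        assert a_n == pytest.approx(1.3 + 0.5)
        assert b_n == pytest.approx(0.8 + 1.0)

    def test_batch_merge_equals_single_pass(self, rng):
        xs = rng.normal(3, 2, 40)
        one = GaussianModel(0.5, 1.0, 2.0, 1.5)
        for x in xs:
            one.add_row(x)
        two = GaussianModel(0.5, 1.0, 2.0, 1.5)
        for x in xs[:17]:
            two.add_row(x)
        for x in xs[17:]:
            two.add_row(x)
        np.testing.assert_allclose(one.posterior(), two.posterior(), rtol=1e-9)

    def test_incremental_matches_batch_statistics(self, rng):
        xs = rng.normal(-1, 0.5, 25)
        m = GaussianModel()
        for x in xs:
            m.add_row(x)
        assert m.mean == pytest.approx(xs.mean(), rel=1e-9)
        assert m.s == pytest.approx(((xs - xs.mean()) ** 2).sum(), rel=1e-9)

    def test_add_remove_roundtrip(self, rng):
        xs = rng.normal(0, 1, 10)
        m = GaussianModel()
        for x in xs:
            m.add_row(x)
        n, mean, s = m.n, m.mean, m.s
        m.add_row(4.2)
        m.remove_row(4.2)
        assert m.n == n
        assert m.mean == pytest.approx(mean, rel=1e-9)
        assert m.s == pytest.approx(s, rel=1e-9)

    def test_remove_from_empty_errors(self):
        with pytest.raises(ValueError):
            GaussianModel().remove_row(1.0)


class TestGaussianPredictive:
    def test_symmetry_about_posterior_location(self):
        m = GaussianModel(mu0=0.0, beta0=1.0, a0=2.0, b0=1.0)
        for x in (1.0, 2.5, -0.3):
            m.add_row(x)
        mu_n = m.posterior()[0]
        for d in (0.3, 1.7):
            assert m.log_predictive(mu_n + d) == pytest.approx(
                m.log_predictive(mu_n - d), abs=1e-12)

    def test_prior_predictive_is_student_t(self):
        # n=0: Student-t, df=2*a0, loc mu0, lam = a0*beta0/(b0*(beta0+1))
        mu0, beta0, a0, b0 = 0.7, 2.0, 1.5, 0.9
        m = GaussianModel(mu0, beta0, a0, b0)
        lam = a0 * beta0 / (b0 * (beta0 + 1.0))
        scale = 1.0 / math.sqrt(lam)
        for x in (-2.0, 0.7, 3.1):
            expected = stats.t.logpdf(x, df=2 * a0, loc=mu0, scale=scale)
            assert m.log_predictive(x) == pytest.approx(expected, abs=1e-10)

    def test_predictive_integrates_to_one(self):
        m = GaussianModel(0.0, 1.0, 1.0, 1.0)
        for x in (0.4, -1.2, 2.0):
            m.add_row(x)
        val, _ = integrate.quad(lambda x: math.exp(m.log_predictive(x)),
                                -60, 60, limit=200)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_non_finite_input_rejected(self):
        m = GaussianModel()
        with pytest.raises(ValueError):
            m.log_predictive(float("nan"))
        with pytest.raises(ValueError):
            m.add_row(float("inf"))


class TestGaussianMarginal:
    def test_empty_marginal_is_zero(self):
        assert GaussianModel().log_marginal() == pytest.approx(0.0)

    def test_single_datum_equals_prior_predictive(self):
        prior = GaussianModel(0.3, 1.2, 2.0, 0.7)
        expected = prior.log_predictive(1.9)
        prior.add_row(1.9)
        assert prior.log_marginal() == pytest.approx(expected, abs=1e-12)

    def test_marginal_agrees_with_2d_quadrature(self, rng):
        mu0, beta0, a0, b0 = 0.2, 1.5, 2.0, 1.2
        xs = rng.normal(0.5, 1.0, 5)
        m = GaussianModel(mu0, beta0, a0, b0)
        for x in xs:
            m.add_row(x)

        def integrand(lam, mu):
            ng = (
                math.sqrt(beta0 * lam / (2 * math.pi))
                * math.exp(-0.5 * beta0 * lam * (mu - mu0) ** 2)
                * b0**a0 / math.gamma(a0) * lam ** (a0 - 1)
                * math.exp(-b0 * lam)
            )
            lik = np.prod(
                np.sqrt(lam / (2 * math.pi))
                * np.exp(-0.5 * lam * (xs - mu) ** 2)
            )
            return ng * lik

        val, _ = integrate.dblquad(integrand, -8, 8, 0, 40,
                                   epsabs=1e-12, epsrel=1e-9)
        assert m.log_marginal() == pytest.approx(math.log(val), abs=1e-5)

    def test_chain_rule_identity_random_permutations(self, rng):
        """Marginal equals the summed sequential predictives for every
        insertion order tried, to 1e-8."""
        for _ in range(25):
            xs = rng.normal(rng.normal(0, 3), rng.uniform(0.2, 2.0),
                            rng.integers(1, 10))
            hyper = (rng.normal(0, 1), rng.uniform(0.5, 3),
                     rng.uniform(0.5, 3), rng.uniform(0.5, 3))
            reference = None
            for _ in range(4):
                order = rng.permutation(len(xs))
                m = GaussianModel(*hyper)
                chained = 0.0
                for x in xs[order]:
                    chained += m.log_predictive(x)
                    m.add_row(x)
                assert m.log_marginal() == pytest.approx(chained, abs=1e-8)
                if reference is None:
                    reference = chained
                assert chained == pytest.approx(reference, abs=1e-8)

    def test_posterior_concentration(self, rng):
        """With heavy data the posterior concentrates on the truth."""
        true_mu, true_sd = 2.0, 0.5
        xs = rng.normal(true_mu, true_sd, 10_000)
        m = GaussianModel(0.0, 1.0, 1.0, 1.0)
        for x in xs:
            m.add_row(x)
        mu_n, beta_n, a_n, b_n = m.posterior()
        se_mu = true_sd / math.sqrt(len(xs))
        assert abs(mu_n - true_mu) < 3 * se_mu
        # posterior mean of the precision approaches 1/sd^2
        prec = a_n / b_n
        se_prec = (1 / true_sd**2) * math.sqrt(2 / len(xs))
        assert abs(prec - 1 / true_sd**2) < 3 * se_prec
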