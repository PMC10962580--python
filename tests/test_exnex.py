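import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import beta as beta_dist

from baskex import (
    BasketData,
    BetaPosterior,
    ModelConfig,
    exclude_heterogeneous,
    exnex_prior_weights,
    fit_exnex,
    fit_mexnex,
    hellinger_beta,
    independent_posterior_quadrature,
)


class TestExclusion:
    def test_trial_data_cutoffs(self, ve):
        assert exclude_heterogeneous(ve, 0.05) == frozenset({3, 4})
        assert exclude_heterogeneous(ve, 0.1) == frozenset({0, 3, 4})

    def test_identical_rates_all_retained(self):
        d = BasketData(n=(13, 13, 13), Y=(4, 4, 4), q0=0.15, q1=0.45)
        assert exclude_heterogeneous(d, 0) == frozenset({0, 1, 2})

    def test_tie_at_cutoff_is_retained(self):
        """A basket at distance exactly c stays (strict > in the rule)."""
        d = BasketData(n=(13, 13), Y=(4, 5), q0=0.15, q1=0.45)  # distance 1/13
        assert exclude_heterogeneous(d, Fraction(1, 13)) == frozenset({0, 1})
        # a float 1/13 must behave identically (exact rational snapping)
        assert exclude_heterogeneous(d, 1 / 13) == frozenset({0, 1})
        # strictly below the distance, both baskets are excluded
        assert exclude_heterogeneous(d, Fraction(1, 13) - Fraction(1, 10**6)) == frozenset()

    def test_requires_two_baskets(self, ve):
        with pytest.raises(ValueError):
            exclude_heterogeneous(BasketData(n=(13,), Y=(2,), q0=0.15, q1=0.45), 0.1)


class TestHellinger:
    def test_identical_densities(self):
        assert hellinger_beta(BetaPosterior(7, 13), BetaPosterior(7, 13)) == 0.0

    def test_published_pair(self):
        # the thyroid/ECD pair of the trial: 1 - h rounds to the printed 0.79
        h = hellinger_beta(BetaPosterior(7, 13), BetaPosterior(3, 6))
        assert h == pytest.approx(0.2136, abs=5e-4)

    def test_disjoint_mass_approaches_one(self):
        assert hellinger_beta(BetaPosterior(1, 100), BetaPosterior(100, 1)) > 0.99

    def test_symmetry(self):
        a, b = BetaPosterior(2.5, 9.0), BetaPosterior(11.0, 3.5)
        assert hellinger_beta(a, b) == pytest.approx(hellinger_beta(b, a), abs=1e-15)

    def test_against_numerical_integration_oracle(self):
        """Closed form vs direct integration of (sqrt f - sqrt g)^2 / 2."""
        rng = np.random.default_rng(2024)
        shapes = rng.uniform(0.5, 50.0, size=(50, 4))
        for a1, b1, a2, b2 in shapes:
            f = beta_dist(a1, b1).pdf
            g = beta_dist(a2, b2).pdf
            h2, _ = integrate.quad(
                lambda x: 0.5 * (math.sqrt(f(x)) - math.sqrt(g(x))) ** 2,
                0.0, 1.0, limit=400,
            )
            oracle = math.sqrt(min(max(h2, 0.0), 1.0))
            closed = hellinger_beta(BetaPosterior(a1, b1), BetaPosterior(a2, b2))
            assert closed == pytest.approx(oracle, abs=1e-6)


class TestPriorWeights:
    def test_trial_data_printed_vectors(self, ve):
        w = exnex_prior_weights(ve, 0.05)
        assert np.round(w.pi, 2).tolist() == [0.0, 0.0, 0.0, 0.79, 0.79]
        w = exnex_prior_weights(ve, 0.1)
        assert np.round(w.pi, 2).tolist() == [0.74, 0.0, 0.0, 0.79, 0.74]

    def test_two_identical_baskets(self):
        d = BasketData(n=(13, 13), Y=(4, 4), q0=0.15, q1=0.45)
        w = exnex_prior_weights(d, 0)
        assert w.pi.tolist() == [1.0, 1.0]  # h = 0 between identical posteriors

    def test_no_partner_means_no_borrowing(self):
        # all pairwise rate differences exceed c: S is empty, all weights 0
        d = BasketData(n=(10, 10, 10), Y=(0, 5, 9), q0=0.15, q1=0.45)
        w = exnex_prior_weights(d, 0.1)
        assert w.retained == frozenset() and np.all(w.pi == 0.0)

    def test_weight_matrix_structure(self, ve):
        w = exnex_prior_weights(ve, 0.1)
        S = sorted(w.retained)
        sub = w.hellinger[np.ix_(S, S)]
        assert np.allclose(sub, sub.T)
        assert np.allclose(np.diag(sub), 0.0)
        assert ((sub >= 0) & (sub <= 1)).all()
        # averaging formula holds exactly on the retained set
        for k in S:
            expected = np.mean([1.0 - w.hellinger[k, j] for j in S if j != k])
            assert w.pi[k] == pytest.approx(expected, abs=1e-12)

    def test_permutation_equivariance(self, ve):
        order = [2, 0, 4, 1, 3]
        w0 = exnex_prior_weights(ve, 0.1)
        w1 = exnex_prior_weights(ve.permuted(order), 0.1)
        assert np.allclose(w1.pi, w0.pi[order], atol=1e-12)
        assert w1.retained == frozenset(order.index(k) for k in w0.retained)

    def test_monotone_sensitivity(self):
        """Pulling one basket away from the others never raises its weight."""
        n = (20, 20, 20)
        prev = None
        for y in (10, 12, 14, 16, 18):
            d = BasketData(n=n, Y=(10, 10, y), q0=0.15, q1=0.45)
            pi = exnex_prior_weights(d, 0.5).pi[2]
            if prev is not None:
                assert pi <= prev + 1e-12
            prev = pi


class TestMixtureFits:
    def test_exact_indicator_boundaries(self, ve, light_settings):
        """pi_k = 0 or 1 forces the posterior indicator to exactly 0 or 1."""
        cfg = ModelConfig.defaults("exnex", pi=(0.0, 1.0, 0.0, 1.0, 0.5))
        r = fit_exnex(ve, cfg, settings=light_settings)
        post = r.extras["posterior_pi"]
        assert post[0] == 0.0 and post[2] == 0.0
        assert post[1] == 1.0 and post[3] == 1.0
        assert 0.0 < post[4] < 1.0

    def test_nex_only_collapse_matches_quadrature(self, ve):
        """All-NEX mixture equals independent fits with the NEX prior."""
        from baskex.posterior import SamplerSettings

        cfg = ModelConfig.defaults("exnex", pi=(0.0,) * 5)
        r = fit_exnex(ve, cfg, settings=SamplerSettings(chains=2, iterations=12_000, burn_in=2_000, seed=11))
        for k in range(ve.K):
            m, s, _ = independent_posterior_quadrature(
                ve.Y[k], ve.n[k], cfg.nex_mean, cfg.nex_variance, ve.q0
            )
            assert r.p_mean[k] == pytest.approx(m, abs=3 * s / math.sqrt(1500) + 0.003)

    def test_mexnex_homogeneous_full_borrowing(self, light_settings):
        """Identical rates with a generous cut-off give weight 1 everywhere."""
        d = BasketData(n=(13, 13, 13), Y=(4, 4, 4), q0=0.15, q1=0.45)
        r = fit_mexnex(d, ModelConfig.defaults("mexnex", c=0.5), settings=light_settings)
        assert np.all(r.extras["prior_pi"] == 1.0)
        assert np.all(r.extras["posterior_pi"] == 1.0)
        assert np.ptp(r.p_mean) < 0.01

    def test_mexnex_excludes_and_reports(self, ve, light_settings):
        r = fit_mexnex(ve, ModelConfig.defaults("mexnex", c=0.05), settings=light_settings)
        assert r.extras["retained"] == [3, 4]
        assert np.all(r.extras["posterior_pi"][:3] == 0.0)

    def test_single_basket_rejected(self):
        d = BasketData(n=(13,), Y=(4,), q0=0.15, q1=0.45)
        with pytest.raises(ValueError):
            fit_exnex(d)
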