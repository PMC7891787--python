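"""Copula families, discrete joint laws, likelihoods, fitting, sampling, KL."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqpop.copulas import (
    FAMILIES,
    CopulaModel,
    PairCopulaModel,
    copula_cdf,
    discrete_joint_pmf,
    fit_copula_parameter,
    kl_empirical_vs_model,
    pair_log_likelihood,
    sample_pair,
    select_family,
)
from seqpop.synth import simulate_pair, simulate_rate_profiles, truncated_poisson_marginals
from seqpop.tensor import SpikeCountTensor, empirical_marginals

PARAMETRIC = [("gumbel", 2.5), ("gaussian", 0.6), ("frank", 4.0),
              ("clayton", 1.7), ("gaussian", -0.5), ("clayton", -0.4)]


class TestCdf:
    def test_independent_is_product(self, rng):
        m = CopulaModel("independent")
        u, v = rng.random(20), rng.random(20)
        np.testing.assert_allclose(copula_cdf(m, u, v), u * v)

    def test_gumbel_theta_one_is_independence(self, rng):
        u, v = rng.random(20), rng.random(20)
        np.testing.assert_allclose(
            copula_cdf(CopulaModel("gumbel", 1.0), u, v), u * v, atol=1e-12)

    def test_frank_small_theta_limit(self, rng):
        u, v = rng.random(20), rng.random(20)
        np.testing.assert_allclose(
            copula_cdf(CopulaModel("frank", 1e-8), u, v), u * v, atol=1e-8)

    def test_gumbel_closed_form_value(self):
        # C(1/2, 1/2 | 2) = 2^(-sqrt(2))
        got = copula_cdf(CopulaModel("gumbel", 2.0), 0.5, 0.5)
        assert got == pytest.approx(2.0 ** (-np.sqrt(2.0)), rel=1e-12)

    @pytest.mark.parametrize("family, theta", PARAMETRIC)
    def test_boundary_contract(self, family, theta, rng):
        m = CopulaModel(family, theta)
        u = rng.random(5)
        np.testing.assert_allclose(copula_cdf(m, u, np.zeros(5)), 0.0, atol=1e-12)
        np.testing.assert_allclose(copula_cdf(m, np.zeros(5), u), 0.0, atol=1e-12)
        np.testing.assert_allclose(copula_cdf(m, u, np.ones(5)), u, atol=1e-12)
        np.testing.assert_allclose(copula_cdf(m, np.ones(5), u), u, atol=1e-12)

    @pytest.mark.parametrize("family, theta", PARAMETRIC)
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_two_increasing_on_random_rectangles(self, family, theta, data):
        unit = st.floats(0.0, 1.0, allow_nan=False)
        u1, u2 = sorted([data.draw(unit), data.draw(unit)])
        v1, v2 = sorted([data.draw(unit), data.draw(unit)])
        m = CopulaModel(family, theta)
        mass = (copula_cdf(m, u2, v2) - copula_cdf(m, u1, v2)
                - copula_cdf(m, u2, v1) + copula_cdf(m, u1, v1))
        assert mass >= -1e-9

    @pytest.mark.parametrize("family, theta", [("gumbel", 2.5), ("frank", 4.0),
                                               ("clayton", 1.7)])
    def test_matches_statsmodels_oracle(self, family, theta, rng):
        from statsmodels.distributions.copula.api import (
            ClaytonCopula, FrankCopula, GumbelCopula)

        oracle = {"gumbel": GumbelCopula, "frank": FrankCopula,
                  "clayton": ClaytonCopula}[family](theta)
        pts = rng.random((25, 2)) * 0.98 + 0.01
        mine = FAMILIES[family].cdf(pts[:, 0], pts[:, 1], theta)
        np.testing.assert_allclose(mine, oracle.cdf(pts), atol=1e-10)

    def test_gaussian_matches_scipy_mvn(self, rng):
        from scipy import special, stats

        theta = -0.6
        mvn = stats.multivariate_normal([0, 0], [[1, theta], [theta, 1]])
        pts = rng.random((10, 2)) * 0.9 + 0.05
        mine = FAMILIES["gaussian"].cdf(pts[:, 0], pts[:, 1], theta)
        ref = mvn.cdf(special.ndtri(pts))
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            CopulaModel("gumbel", 0.5)
        with pytest.raises(ValueError):
            CopulaModel("gaussian", 1.5)
        with pytest.raises(ValueError):
            CopulaModel("clayton", 0.0)
        with pytest.raises(ValueError):
            CopulaModel("nopula", 1.0)


class TestDiscreteJoint:
    def test_independent_is_outer_product(self):
        px = np.array([0.2, 0.5, 0.3])
        py = np.array([0.6, 0.4])
        law = discrete_joint_pmf(CopulaModel("independent"),
                                 np.cumsum(px), np.cumsum(py))
        np.testing.assert_allclose(law.pmf, np.outer(px, py), atol=1e-12)

    def test_gaussian_bernoulli_orthant_closed_form(self):
        # both margins Bernoulli(1/2), theta = 1/2:
        # P(1,1) = 1/4 + arcsin(1/2) / (2 pi) = 1/3
        law = discrete_joint_pmf(CopulaModel("gaussian", 0.5),
                                 [0.5, 1.0], [0.5, 1.0])
        assert law.pmf[1, 1] == pytest.approx(1.0 / 3.0, abs=1e-10)

    @pytest.mark.parametrize("family, theta", PARAMETRIC)
    def test_marginals_reproduced(self, family, theta, rng):
        px = rng.dirichlet(np.ones(4))
        py = rng.dirichlet(np.ones(5))
        law = discrete_joint_pmf(CopulaModel(family, theta),
                                 np.cumsum(px), np.cumsum(py))
        assert law.pmf.min() >= 0
        assert law.pmf.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(law.marginal_x(), px, atol=1e-10)
        np.testing.assert_allclose(law.marginal_y(), py, atol=1e-10)

    def test_non_monotone_cdf_rejected(self):
        with pytest.raises(ValueError):
            discrete_joint_pmf(CopulaModel("independent"),
                               [0.5, 0.4, 1.0], [0.5, 1.0])


class TestLikelihood:
    def _toy_pair(self, rng, theta=2.0, T=2, R=25):
        rates = np.full(T, 0.8)
        t = simulate_pair(rates, rates, "gumbel", theta, R, seed=int(rng.integers(2**31)))
        m = empirical_marginals(t)
        return t, m

    def test_independent_factorises(self, rng):
        t, m = self._toy_pair(rng)
        ll = pair_log_likelihood(CopulaModel("independent"),
                                 t.counts[0], t.counts[1], (m.pmf[0], m.pmf[1]))
        # marginal log-likelihoods
        ll_marg = 0.0
        for cell in range(2):
            for tt in range(t.n_bins):
                for r in range(t.n_reps):
                    ll_marg += np.log(m.pmf[cell, tt, t.counts[cell, tt, r]])
        assert ll == pytest.approx(ll_marg, rel=1e-10)

    def test_gumbel_theta_one_equals_independent(self, rng):
        t, m = self._toy_pair(rng)
        args = (t.counts[0], t.counts[1], (m.pmf[0], m.pmf[1]))
        assert pair_log_likelihood(CopulaModel("gumbel", 1.0), *args) == \
            pytest.approx(pair_log_likelihood(CopulaModel("independent"), *args))

    def test_matches_full_table_summation_oracle(self, rng):
        t, m = self._toy_pair(rng)
        model = CopulaModel("gumbel", 2.3)
        got = pair_log_likelihood(model, t.counts[0], t.counts[1],
                                  (m.pmf[0], m.pmf[1]))
        oracle = 0.0
        for tt in range(t.n_bins):
            law = discrete_joint_pmf(model, m.cdf[0, tt], m.cdf[1, tt])
            for r in range(t.n_reps):
                oracle += np.log(law.pmf[t.counts[0, tt, r], t.counts[1, tt, r]])
        assert got == pytest.approx(oracle, rel=1e-10)


class TestFit:
    def test_recovers_gumbel_theta(self):
        rates = simulate_rate_profiles(2, 300, seed=21, mean_rate=1 / 6)
        t = simulate_pair(rates[0], rates[1], "gumbel", 3.0, 79, seed=22)
        marg = truncated_poisson_marginals(rates, t.n_max)
        fit = fit_copula_parameter("gumbel", t.counts[0], t.counts[1],
                                   (marg.pmf[0], marg.pmf[1]))
        assert fit.converged
        assert fit.theta == pytest.approx(3.0, rel=0.12)

    def test_independent_data_pushes_theta_to_boundary(self):
        rates = simulate_rate_profiles(2, 200, seed=23, mean_rate=1 / 4)
        t = simulate_pair(rates[0], rates[1], "independent", None, 79, seed=24)
        marg = truncated_poisson_marginals(rates, t.n_max)
        fit = fit_copula_parameter("gumbel", t.counts[0], t.counts[1],
                                   (marg.pmf[0], marg.pmf[1]))
        assert fit.theta == pytest.approx(1.0, abs=0.05)

    def test_fitted_likelihood_dominates_independence(self, rng):
        rates = np.full(40, 0.7)
        t = simulate_pair(rates, rates, "gumbel", 2.0, 40, seed=25)
        model = PairCopulaModel(t.counts[0], t.counts[1], "gumbel")
        fit = model.fit()
        assert fit.llf >= model.loglike(1.0) - 1e-9

    def test_no_informative_bins_rejected(self):
        counts = np.zeros((2, 4, 6), dtype=int)
        t = SpikeCountTensor(counts, 17.0)
        with pytest.raises(ValueError, match="informative"):
            fit_copula_parameter("gumbel", t.counts[0], t.counts[1])

    def test_summary_mentions_family_and_theta(self):
        rates = np.full(30, 0.8)
        t = simulate_pair(rates, rates, "gumbel", 2.0, 30, seed=26)
        s = fit_copula_parameter("gumbel", t.counts[0], t.counts[1]).summary()
        assert "gumbel" in s and "log-likelihood" in s


class TestSampling:
    @pytest.mark.parametrize("family, theta", [("gumbel", 2.0), ("frank", 4.0),
                                               ("clayton", 1.7),
                                               ("gaussian", 0.6)])
    def test_samples_match_exact_table(self, family, theta):
        model = CopulaModel(family, theta)
        cdf_x = np.array([0.45, 0.8, 0.95, 1.0])
        cdf_y = np.array([0.55, 0.85, 1.0])
        law = discrete_joint_pmf(model, cdf_x, cdf_y)
        x, y = sample_pair(model, cdf_x, cdf_y, 100_000, seed=5)
        emp = np.zeros_like(law.pmf)
        np.add.at(emp, (x, y), 1.0 / x.size)
        tv = 0.5 * np.abs(emp - law.pmf).sum()
        assert tv < 0.01

    def test_independent_marginals_preserved(self):
        model = CopulaModel("independent")
        cdf = np.array([0.3, 0.7, 1.0])
        x, y = sample_pair(model, cdf, cdf, 50_000, seed=6)
        for vals in (x, y):
            emp = np.bincount(vals, minlength=3) / vals.size
            np.testing.assert_allclose(emp, np.diff(np.r_[0, cdf]), atol=0.01)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.02

    def test_seeded_determinism(self):
        model = CopulaModel("gumbel", 2.0)
        cdf = np.array([0.5, 0.9, 1.0])
        a = sample_pair(model, cdf, cdf, 100, seed=9)
        b = sample_pair(model, cdf, cdf, 100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestKL:
    def test_zero_when_model_equals_empirical(self, rng):
        # independent model with the tensor's own empirical marginals on
        # data that is conditionally independent given the bin
        counts = np.repeat(rng.integers(0, 3, size=(2, 6, 1)), 8, axis=2)
        t = SpikeCountTensor(counts, 17.0)
        m = empirical_marginals(t)
        kl = kl_empirical_vs_model(t.counts[0], t.counts[1],
                                   CopulaModel("independent"),
                                   (m.pmf[0], m.pmf[1]))
        assert kl == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, rng):
        rates = np.full(20, 0.8)
        t = simulate_pair(rates, rates, "gumbel", 2.5, 50, seed=31)
        m = empirical_marginals(t)
        for family, theta in PARAMETRIC:
            kl = kl_empirical_vs_model(t.counts[0], t.counts[1],
                                       CopulaModel(family, theta),
                                       (m.pmf[0], m.pmf[1]))
            assert kl >= 0

    def test_true_family_beats_independence(self):
        wins = 0
        n_rep = 10
        for s in range(n_rep):
            rates = np.full(60, 0.8)
            t = simulate_pair(rates, rates, "gumbel", 3.0, 79, seed=40 + s)
            m = empirical_marginals(t)
            pm = (m.pmf[0], m.pmf[1])
            fit = fit_copula_parameter("gumbel", t.counts[0], t.counts[1], pm)
            kl_g = kl_empirical_vs_model(t.counts[0], t.counts[1], fit.model, pm)
            kl_i = kl_empirical_vs_model(t.counts[0], t.counts[1],
                                         CopulaModel("independent"), pm)
            wins += kl_g < kl_i
        assert wins >= int(0.95 * n_rep)


class TestFamilySelection:
    def test_gumbel_ranked_first_on_gumbel_data(self):
        rates = simulate_rate_profiles(4, 80, seed=51, mean_rate=0.3)
        cells = []
        for i in range(0, 4, 2):
            t = simulate_pair(rates[i], rates[i + 1], "gumbel", 3.0, 60,
                              seed=52 + i)
            cells.append(t.counts)
        counts = np.concatenate(cells, axis=0)
        tensor = SpikeCountTensor(counts, 17.0)
        table = select_family(tensor, pairs=[(0, 1), (2, 3)],
                              families=("independent", "gumbel", "gaussian"))
        assert table.iloc[0]["family"] == "gumbel"

    def test_ranking_invariant_to_pair_ordering(self, rng):
        counts = rng.integers(0, 3, size=(3, 10, 30))
        tensor = SpikeCountTensor(counts, 17.0)
        t1 = select_family(tensor, pairs=[(0, 1), (1, 2)],
                           families=("independent", "gumbel"))
        t2 = select_family(tensor, pairs=[(1, 2), (0, 1)],
                           families=("independent", "gumbel"))
        assert list(t1["family"]) == list(t2["family"])
        np.testing.assert_allclose(t1["mean_kl"], t2["mean_kl"])
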