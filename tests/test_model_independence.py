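import numpy as np
import pytest
from scipy import stats

from operonmeta.io_data import MetaDataset, standardize_slides
from operonmeta.model_independence import (
    McmcConfig,
    indicator_probability,
    init_state,
    normal_posterior,
    run_chain,
    sample_p,
    sample_variance,
)
from operonmeta.priors import PriorSpec, StudyPriors, elicit_priors
from operonmeta.simulate import simulate_paper_scenario

from conftest import make_oligo, make_spotted
from oracles import grid_conditional_moments


def default_priors(n_studies=1, probe_var=None, **kw):
    sp = StudyPriors(slide_df=3, slide_scale=0.5, exp_df=3, exp_scale=0.5,
                     probe_var=probe_var)
    return PriorSpec(studies=[sp] * n_studies, **kw)


class TestConjugateMeanUpdates:
    """The probe / experiment / gene mean conditionals are the same
    normal-normal form; each case is checked against grid quadrature of the
    unnormalised conditional density."""

    @pytest.mark.parametrize("data,data_var,prior_mean,prior_var,expect", [
        # one probe value 2, equal precision: N(1, 0.5)
        ([2.0], 1.0, 0.0, 1.0, (1.0, 0.5)),
        # two probes (1,3), probe var 2, slide prior N(1,4): N(1.8, 0.8)
        ([1.0, 3.0], 2.0, 1.0, 4.0, (1.8, 0.8)),
        # three experiment means, exp var 0.5, slab prior: N(0.96, 0.16)
        ([0.5, 1.0, 1.5], 0.5, 0.0, 4.0, (0.96, 0.16)),
        # operon-style: two values, prior N(3, 0.5): N(2.25, 0.25)
        ([1.0, 2.0], 1.0, 3.0, 0.5, (2.25, 0.25)),
    ])
    def test_matches_grid_quadrature(self, data, data_var, prior_mean, prior_var, expect):
        mean, var = normal_posterior(
            np.sum(data), len(data), data_var, prior_mean, prior_var
        )
        assert (mean, var) == pytest.approx(expect)
        g_mean, g_var = grid_conditional_moments(data, data_var, prior_mean, prior_var)
        assert mean == pytest.approx(g_mean, abs=1e-6)
        assert var == pytest.approx(g_var, rel=1e-4)

    def test_flat_prior_limit_returns_data_mean(self):
        mean, var = normal_posterior(4.0, 2, 1.0, 0.0, 1e12)
        assert mean == pytest.approx(2.0, abs=1e-9)
        assert var == pytest.approx(0.5, rel=1e-6)

    def test_tight_prior_limit_collapses_to_prior(self):
        mean, _ = normal_posterior(100.0, 10, 1.0, 0.0, 1e-12)
        assert abs(mean) < 1e-6

    def test_symmetric_data_keeps_prior_mean(self):
        mean, _ = normal_posterior(2.0 + 0.0, 2, 2.0, 1.0, 4.0)
        assert mean == pytest.approx(1.0)


class TestVarianceUpdate:
    def test_posterior_mean_matches_scaled_invchi2(self):
        # prior (3, 1) with residuals (1, -1): df 5, scale 1, mean 5/3
        rng = np.random.default_rng(0)
        draws = np.array([sample_variance(rng, 3, 1.0, 2.0, 2) for _ in range(200_000)])
        assert draws.mean() == pytest.approx(5 / 3, rel=0.02)

    def test_zero_residual_closed_form_scale(self):
        # SS = 0 with m terms: scale nu0*s0/(nu0+m); check via the median,
        # which is finite even at small df
        rng = np.random.default_rng(1)
        nu0, s0, m = 3, 2.0, 7
        draws = np.array([sample_variance(rng, nu0, s0, 0.0, m) for _ in range(100_000)])
        df = nu0 + m
        scale = nu0 * s0 / df
        expected_median = df * scale / stats.chi2.median(df)
        assert np.median(draws) == pytest.approx(expected_median, rel=0.02)

    def test_no_data_draws_from_prior(self):
        rng = np.random.default_rng(2)
        draws = np.array([sample_variance(rng, 3, 1.0, 0.0, 0) for _ in range(100_000)])
        expected_median = 3 * 1.0 / stats.chi2.median(3)
        assert np.median(draws) == pytest.approx(expected_median, rel=0.02)


class TestIndicatorUpdate:
    def test_density_ratio_single_study(self):
        # theta = 0, p = 0.5: 0.12616 / (3.98942 + 0.12616)
        prob = indicator_probability(np.array([[0.0]]), 0.5, 0.01, 10.0)
        expected = stats.norm.pdf(0, scale=np.sqrt(10)) / (
            stats.norm.pdf(0, scale=0.1) + stats.norm.pdf(0, scale=np.sqrt(10))
        )
        assert prob[0] == pytest.approx(expected, rel=1e-6)
        assert prob[0] == pytest.approx(0.0307, abs=2e-4)

    def test_equal_variances_return_p(self):
        prob = indicator_probability(np.array([[0.3, -2.0]]), 0.2, 1.0, 1.0 + 1e-12)
        np.testing.assert_allclose(prob, 0.2, atol=1e-6)

    def test_large_effect_saturates(self):
        prob = indicator_probability(np.array([[50.0]]), 0.5, 0.01, 10.0)
        assert prob[0] > 1 - 1e-12

    def test_inflation_widens_both_components(self):
        # with sampling variance added, the same observed mean is less
        # decisive than when conditioning on the latent mean itself
        sharp = indicator_probability(np.array([[1.0]]), 0.1, 0.01, 4.0)
        blurred = indicator_probability(np.array([[1.0]]), 0.1, 0.01, 4.0, inflation=1.0)
        assert blurred[0] < sharp[0]

    def test_density_ratio_two_studies(self):
        prob = indicator_probability(np.zeros((2, 1)), 0.5, 0.01, 10.0)
        assert prob[0] == pytest.approx(0.00100, abs=5e-5)


class TestPUpdate:
    def test_conjugate_counting(self):
        rng = np.random.default_rng(3)
        draws = np.array([sample_p(rng, 1, 1, 150, 3000) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(151 / 3002, rel=0.01)

    def test_no_de_units(self):
        rng = np.random.default_rng(4)
        draws = np.array([sample_p(rng, 1, 1, 0, 3000) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(1 / 3002, rel=0.05)


class TestInitState:
    def test_empirical_means(self):
        study = make_spotted(np.array([-1.0, 0.0, 1.0]).reshape(1, 1, 3))
        ds = MetaDataset(studies=[study])
        state = init_state(ds, default_priors(), seed=0)
        assert state.mu[0][0, 0] == pytest.approx(0.0)
        assert state.theta[0, 0] == pytest.approx(0.0)
        assert state.p == pytest.approx(0.5)

    def test_same_seed_bit_identical(self, micro_dataset):
        s1 = init_state(micro_dataset, default_priors(), seed=9)
        s2 = init_state(micro_dataset, default_priors(), seed=9)
        np.testing.assert_array_equal(s1.theta, s2.theta)
        assert s1.rng.standard_normal() == s2.rng.standard_normal()

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError, match="slab"):
            default_priors(tau0_sq=4.0, tau1_sq=0.01)


class TestRunChain:
    def test_same_seed_identical_posterior(self, micro_dataset):
        cfg = McmcConfig(iterations=200, burn_in=50, thinning=2, seed=5)
        r1 = run_chain(micro_dataset, default_priors(), cfg)
        r2 = run_chain(micro_dataset, default_priors(), cfg)
        np.testing.assert_array_equal(r1.D, r2.D)
        np.testing.assert_array_equal(r1.p_draws, r2.p_draws)

    def test_retained_draw_count(self, micro_dataset):
        cfg = McmcConfig(iterations=103, burn_in=3, thinning=10, seed=0)
        r = run_chain(micro_dataset, default_priors(), cfg)
        assert r.n_retained == 10

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="iterations > burn_in"):
            McmcConfig(iterations=100, burn_in=100)

    def test_null_simulation_keeps_posterior_low(self):
        ds, _ = simulate_paper_scenario("two_study", 0.0, seed=3, n_genes=500)
        r = run_chain(ds, elicit_priors(ds), McmcConfig(1500, 300, 3, 3))
        assert r.D.mean() < 0.2

    def test_extreme_gene_is_detected(self):
        # 200 null genes plus one with theta = 3 in both studies
        rng = np.random.default_rng(8)
        G = 201
        theta = np.zeros(G)
        theta[0] = 3.0
        s1 = make_spotted(
            theta[:, None, None]
            + 0.5 * rng.normal(size=(G, 3, 1))
            + 0.5 * rng.normal(size=(G, 3, 2)),
        )
        s2 = make_oligo(
            theta[:, None, None, None]
            + 0.5 * rng.normal(size=(G, 2, 1, 1))
            + 0.5 * rng.normal(size=(G, 2, 2, 1))
            + 0.6 * rng.normal(size=(G, 2, 2, 4)),
        )
        ds = MetaDataset(studies=[standardize_slides(s1), standardize_slides(s2)])
        r = run_chain(ds, elicit_priors(ds), McmcConfig(1500, 300, 3, 8))
        assert r.D[0] > 0.95
        assert r.D.mean() < 0.2

    def test_gene_reordering_equivariance(self):
        # reordering genes permutes D up to Monte-Carlo noise; ranks of
        # clearly separated genes must agree
        ds, truth = simulate_paper_scenario("two_study", 0.10, seed=6, n_genes=150)
        perm = np.random.default_rng(1).permutation(150)
        studies_p = [s.subset_genes(perm) for s in ds.studies]
        # relabel so the permuted dataset passes gene-order validation
        for s in studies_p:
            s.genes = [f"g{i:05d}" for i in range(150)]
        ds_p = MetaDataset(studies=studies_p)
        cfg = McmcConfig(2500, 500, 4, 2)
        r = run_chain(ds, elicit_priors(ds), cfg)
        r_p = run_chain(ds_p, elicit_priors(ds_p), cfg)
        assert np.mean(np.abs(r.D[perm] - r_p.D)) < 0.1
        assert np.sum((r.D[perm] > 0.5) != (r_p.D > 0.5)) <= 5
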