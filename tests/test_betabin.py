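"""Beta-binomial distribution, likelihood fits, rho estimators, simulator."""

import numpy as np
import pytest
from scipy import stats

from rrmeta import (
    BBParams,
    MetaDataset,
    SimDesign,
    StudyTable,
    bb_loglik,
    bb_pmf,
    estimate_rho,
    fit_bb_logit,
    fit_bb_ml,
    pool_bb_iv,
    replicate_rng,
    simulate_bb,
)
from rrmeta.betabin import run_bb_simulation
from rrmeta.effects import dataset_effects
from rrmeta.rem import pool


class TestBBParams:
    def test_alpha_beta_mapping(self):
        p = BBParams(0.3, 0.1)
        assert p.alpha == pytest.approx(0.3 * 9)
        assert p.beta == pytest.approx(0.7 * 9)
        assert p.gamma == pytest.approx(9.0)

    def test_variance_inflation(self):
        p = BBParams(0.3, 0.1)
        assert p.var(20) == pytest.approx(20 * 0.3 * 0.7 * (1 + 19 * 0.1))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            BBParams(0.0, 0.1)
        with pytest.raises(ValueError):
            BBParams(0.3, 1.0)


class TestBBPmf:
    @pytest.mark.parametrize("n,pi,rho", [(20, 0.3, 0.1), (7, 0.9, 0.4), (50, 0.05, 0.02)])
    def test_normalization(self, n, pi, rho):
        y = np.arange(n + 1)
        assert bb_pmf(y, n, pi, rho).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_betabinom(self):
        n, pi, rho = 25, 0.35, 0.15
        p = BBParams(pi, rho)
        y = np.arange(n + 1)
        np.testing.assert_allclose(
            bb_pmf(y, n, pi, rho), stats.betabinom(n, p.alpha, p.beta).pmf(y),
            rtol=1e-10)

    def test_binomial_limit_as_rho_vanishes(self):
        n, pi = 15, 0.4
        y = np.arange(n + 1)
        np.testing.assert_allclose(
            bb_pmf(y, n, pi, 1e-8), stats.binom(n, pi).pmf(y), rtol=1e-5)
        np.testing.assert_allclose(
            bb_pmf(y, n, pi, 0.0), stats.binom(n, pi).pmf(y), rtol=1e-12)

    def test_bernoulli_case_ignores_rho(self):
        for rho in (0.0, 0.3, 0.9):
            assert bb_pmf(1, 1, 0.27, rho) == pytest.approx(0.27)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bb_pmf(5, 4, 0.3, 0.1)


class TestBBLoglik:
    def test_single_study_rho_zero_is_binomial(self):
        ds = MetaDataset((StudyTable(3, 10, 6, 12),))
        expected = (
            stats.binom(10, 0.25).logpmf(3) + stats.binom(12, 0.5).logpmf(6)
        )
        assert bb_loglik(ds, 0.5, 0.25, 0.0) == pytest.approx(float(expected))

    def test_stable_for_large_arms(self, diuretics):
        # includes an n = 1011 arm; no overflow / nan
        val = bb_loglik(diuretics, 0.143, 0.185, 0.138)
        assert np.isfinite(val)

    def test_fitted_point_is_local_maximum(self, diuretics):
        base = bb_loglik(diuretics, 0.143, 0.185, 0.138)
        for d_t, d_c, d_r in ((0.02, 0, 0), (0, 0.02, 0), (0, 0, 0.05),
                              (-0.02, 0, 0), (0, -0.02, 0), (0, 0, -0.05)):
            assert bb_loglik(diuretics, 0.143 + d_t, 0.185 + d_c, 0.138 + d_r) <= base


class TestMLFits:
    def test_direct_fit_reproduces_published_diuretics(self, diuretics):
        f = fit_bb_ml(diuretics)
        assert f.rho == pytest.approx(0.138, abs=5e-3)
        assert f.pi_t == pytest.approx(0.143, abs=5e-3)
        assert f.pi_c == pytest.approx(0.185, abs=5e-3)
        assert f.rr == pytest.approx(0.774, abs=5e-3)
        assert f.converged

    def test_direct_fit_reproduces_published_tca(self, tca):
        f = fit_bb_ml(tca)
        assert f.rho == pytest.approx(0.175, abs=5e-3)
        assert f.pi_t == pytest.approx(0.593, abs=5e-3)
        assert f.pi_c == pytest.approx(0.347, abs=5e-3)
        assert f.rr == pytest.approx(1.708, abs=5e-3)

    def test_logit_fit_reaches_same_maximum(self, diuretics, tca):
        for ds in (diuretics, tca):
            a = fit_bb_ml(ds)
            b = fit_bb_logit(ds)
            assert b.loglik == pytest.approx(a.loglik, abs=1e-6)
            assert b.pi_t == pytest.approx(a.pi_t, abs=1e-4)
            assert b.pi_c == pytest.approx(a.pi_c, abs=1e-4)

    def test_delta_method_variances_differ_between_links(self, diuretics):
        a = fit_bb_ml(diuretics)
        b = fit_bb_logit(diuretics)
        assert a.var_log_rr != pytest.approx(b.var_log_rr, rel=1e-3)
        # direct-link CI reproduces the published (-1.008, 0.495)
        lo, hi = a.ci_log_rr
        assert lo == pytest.approx(-1.008, abs=5e-3)
        assert hi == pytest.approx(0.495, abs=5e-3)

    def test_covariance_symmetric_psd(self, diuretics):
        f = fit_bb_ml(diuretics)
        np.testing.assert_allclose(f.cov, f.cov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(f.cov) > -1e-10)

    def test_unidentifiable_arm_rejected(self):
        ds = MetaDataset((StudyTable(0, 10, 3, 12), StudyTable(0, 8, 2, 9)))
        with pytest.raises(ValueError, match="no events"):
            fit_bb_ml(ds)


class TestRhoEstimators:
    def test_mp_and_bd_reproduce_published_diuretics(self, diuretics):
        assert estimate_rho(diuretics, "MP").rho == pytest.approx(0.016, abs=5e-3)
        bd = estimate_rho(diuretics, "BD")
        assert bd.rho == pytest.approx(0.019, abs=5e-3)
        # inverted chi-squared interval close to the published (0.003, 0.106)
        assert bd.ci_low == pytest.approx(0.003, abs=2e-3)
        assert bd.ci_high == pytest.approx(0.106, abs=8e-3)

    def test_mom_reml_reproduce_published_values(self, diuretics, tca):
        assert estimate_rho(diuretics, "MoM").rho == pytest.approx(0.008, abs=5e-3)
        assert estimate_rho(diuretics, "REML").rho == pytest.approx(0.010, abs=5e-3)
        assert estimate_rho(tca, "MoM").rho == pytest.approx(0.028, abs=5e-3)
        assert estimate_rho(tca, "MP").rho == pytest.approx(0.026, abs=5e-3)
        assert estimate_rho(tca, "REML").rho == pytest.approx(0.031, abs=5e-3)

    def test_near_zero_under_homogeneous_binomial_data(self):
        rng = np.random.default_rng(77)
        hits_zero = 0
        for rep in range(40):
            studies = tuple(
                StudyTable(int(rng.binomial(100, 0.2)), 100,
                           int(rng.binomial(100, 0.25)), 100, str(j))
                for j in range(10)
            )
            ds = MetaDataset(studies)
            rho = estimate_rho(ds, "MP").rho
            assert rho < 0.08
            hits_zero += rho == 0.0
        # the zero truncation engages a nontrivial fraction of the time
        assert 5 <= hits_zero <= 35

    def test_requires_two_studies(self, diuretics):
        with pytest.raises(ValueError, match="K >= 2"):
            estimate_rho(MetaDataset(diuretics.studies[:1]), "MP")

    def test_unknown_method(self, diuretics):
        with pytest.raises(ValueError, match="unknown rho"):
            estimate_rho(diuretics, "XYZ")


class TestPoolBBIV:
    def test_rho_zero_equals_half_corrected_fixed_effect(self, diuretics):
        res = pool_bb_iv(diuretics, 0.0)
        theta, v, _ = dataset_effects(diuretics, estimator="pettigrew")
        ref = pool(theta, v, 0.0)
        assert res.theta_hat == pytest.approx(ref.theta_hat)
        assert res.se == pytest.approx(ref.se)

    def test_tca_published_values(self, tca):
        mp = pool_bb_iv(tca, estimate_rho(tca, "MP"))
        assert mp.theta_hat == pytest.approx(0.368, abs=5e-3)
        assert mp.rr == pytest.approx(1.445, abs=7e-3)


class TestSimulateBB:
    def test_variance_matches_bb_moment_formula(self):
        d = SimDesign(k=4000, n=1000, theta=0.0, pi_c=0.3, rho=0.1,
                      option="bb", reps=1, seed=13)
        repl = simulate_bb(d, replicate_rng(d.seed, 0))
        y_c = np.array([s.y_c for s in repl.dataset])
        expected = BBParams(0.3, 0.1).var(500)
        assert y_c.var(ddof=1) == pytest.approx(expected, rel=0.08)
        assert y_c.mean() == pytest.approx(500 * 0.3, rel=0.02)

    def test_rho_zero_is_plain_binomial(self):
        d = SimDesign(k=2000, n=200, theta=0.0, pi_c=0.2, rho=0.0,
                      option="bb", reps=1, seed=3)
        repl = simulate_bb(d, replicate_rng(d.seed, 0))
        y = np.array([s.y_t for s in repl.dataset])
        assert y.var(ddof=1) == pytest.approx(100 * 0.2 * 0.8, rel=0.1)

    def test_seeded_determinism(self):
        d = SimDesign(k=10, n=100, theta=0.2, pi_c=0.2, rho=0.1,
                      option="bb", reps=1, seed=21)
        a = simulate_bb(d, replicate_rng(d.seed, 0))
        b = simulate_bb(d, replicate_rng(d.seed, 0))
        assert [(s.y_c, s.y_t) for s in a.dataset] == [(s.y_c, s.y_t) for s in b.dataset]

    def test_design_violating_probability_bound_rejected(self):
        with pytest.raises(ValueError, match="pi_c"):
            SimDesign(k=5, n=100, theta=1.5, pi_c=0.3, rho=0.1, option="bb")


def test_bb_simulation_driver_recovers_rho_and_theta():
    """Direct ML is near-unbiased at theta = 0 (small run; scaled design)."""
    d = SimDesign(k=20, n=500, theta=0.0, pi_c=0.3, rho=0.1,
                  option="bb", reps=40, seed=17)
    res = run_bb_simulation(d, methods=("MP", "ML"))
    assert abs(res.bias_theta["ML"]) < 4 * res.mcse_theta["ML"] + 0.01
    assert abs(res.bias_theta["MP"]) < 4 * res.mcse_theta["MP"] + 0.01
    assert abs(res.bias_het["ML"]) < 4 * res.mcse_het["ML"] + 0.01
    assert res.n_failed == 0
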