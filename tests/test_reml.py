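import numpy as np
import pandas as pd
import pytest

from rrnorm import (
    ModelDesign,
    VarianceComponents,
    build_design,
    compare_fits,
    fit_reml,
    lrt,
    reml_loglik,
    solve_mme,
)

from _oracles import balanced_oneway_blup, balanced_oneway_reml, dense_reml_loglik
from conftest import random_varcomps


def oneway_design(y2d):
    """Wrap a (groups, per-group) response as a random-intercept design."""
    g, n = y2d.shape
    y = y2d.ravel()
    ids = np.repeat([f"g{i}" for i in range(g)], n)
    return ModelDesign(
        y=y, X=np.ones((g * n, 1)), fixed_names=["mu"],
        Zc=np.ones((g * n, 1)), coef_names=["ind_0"],
        year_codes=np.full(g * n, -1), year_levels=[],
        ind_ids=ids, resid_class=np.zeros(g * n, int),
        trait_indicator=np.zeros(g * n, int),
    )


class TestLoglikOracle:
    def test_matches_dense_oracle_on_tiny_designs(self, tiny_designs):
        rng = np.random.default_rng(42)
        for design in tiny_designs:
            for _ in range(4):
                vc = random_varcomps(design.q_coef, rng,
                                     include_year=design.include_year)
                got = reml_loglik(design, vc)
                want = dense_reml_loglik(design, vc)
                assert got == pytest.approx(want, abs=1e-8)

    def test_zero_random_limit_equals_fixed_regression(self, tiny_designs):
        # with G = 0 and no year variance the model is y ~ X beta + e
        design = next(d for d in tiny_designs if d.q_coef and not d.meta["bivariate"])
        vc = VarianceComponents(G=np.zeros((design.q_coef, design.q_coef)),
                                sigma2_year=0.0, sigma2_resid=0.5)
        vc_none = VarianceComponents(G=None, sigma2_year=None, sigma2_resid=0.5)
        stripped = ModelDesign(
            y=design.y, X=design.X, fixed_names=design.fixed_names, Zc=None,
            coef_names=[], year_codes=np.full(design.n_obs, -1), year_levels=[],
            ind_ids=design.ind_ids, resid_class=design.resid_class,
            trait_indicator=design.trait_indicator)
        assert reml_loglik(design, vc) == pytest.approx(
            reml_loglik(stripped, vc_none), abs=1e-8)

    def test_response_shift_invariance(self, tiny_designs):
        # adding a constant changes only the intercept, not the restricted
        # likelihood (intercept is in the fixed effects)
        design = next(d for d in tiny_designs if d.q_coef)
        rng = np.random.default_rng(3)
        vc = random_varcomps(design.q_coef, rng, include_year=design.include_year)
        shifted = ModelDesign(
            y=design.y + 5.0, X=design.X, fixed_names=design.fixed_names,
            Zc=design.Zc, coef_names=design.coef_names,
            year_codes=design.year_codes, year_levels=design.year_levels,
            ind_ids=design.ind_ids, resid_class=design.resid_class,
            trait_indicator=design.trait_indicator, meta=design.meta)
        assert reml_loglik(shifted, vc) == pytest.approx(
            reml_loglik(design, vc), abs=1e-7)

    def test_non_pd_covariance_returns_minus_inf(self, tiny_designs):
        # a negative residual variance makes the observation covariance
        # indefinite; the likelihood must signal -inf instead of raising
        design = next(d for d in tiny_designs if d.q_coef == 2)
        vc = VarianceComponents(G=np.zeros((2, 2)), sigma2_year=0.0,
                                sigma2_resid=-0.5)
        assert reml_loglik(design, vc) == -np.inf


class TestBalancedOneWay:
    def test_fit_matches_anova_reml_closed_form(self):
        rng = np.random.default_rng(5)
        y = 2.0 + rng.normal(0, 0.8, (10, 5)) + rng.normal(0, 0.6, 10)[:, None]
        s2g, s2e = balanced_oneway_reml(y)
        fit = fit_reml(oneway_design(y), n_starts=2, seed=0, compute_se=False)
        assert fit.converged
        assert fit.varcomps.G[0, 0] == pytest.approx(s2g, abs=1e-6)
        assert fit.varcomps.sigma2_resid == pytest.approx(s2e, abs=1e-6)

    def test_blup_matches_shrinkage_estimator(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, (8, 4)) + rng.normal(0, 0.9, 8)[:, None]
        s2g, s2e = balanced_oneway_reml(y)
        vc = VarianceComponents(G=np.array([[s2g]]), sigma2_year=None,
                                sigma2_resid=s2e)
        _, _, blups, _ = solve_mme(oneway_design(y), vc)
        want = balanced_oneway_blup(y, s2g, s2e)
        assert blups["ind_0"].to_numpy() == pytest.approx(want, abs=1e-8)


class TestSolveMme:
    def test_zero_g_shrinks_blups_to_zero(self, tiny_designs):
        design = next(d for d in tiny_designs if d.q_coef and not d.meta["bivariate"])
        vc = VarianceComponents(G=np.zeros((design.q_coef, design.q_coef)),
                                sigma2_year=0.1, sigma2_resid=0.5)
        _, _, blups, _ = solve_mme(design, vc)
        assert np.allclose(blups.to_numpy(), 0.0)

    def test_blup_elevations_sum_to_near_zero(self, small_order1_fit):
        total = small_order1_fit.blups["ind_0"].sum()
        scale = small_order1_fit.blups["ind_0"].abs().sum() + 1.0
        assert abs(total) / scale < 0.05


class TestFitReml:
    def test_refit_from_optimum_is_fixed_point(self, small_order1_fit):
        fit2 = fit_reml(small_order1_fit.design, init=small_order1_fit.varcomps,
                        compute_se=False)
        assert fit2.logL == pytest.approx(small_order1_fit.logL, abs=1e-5)

    def test_one_record_per_individual_flags_nonidentifiable(self):
        # intercept-only individuals with a single record each alias the
        # individual variance with the residual
        rng = np.random.default_rng(2)
        n = 40
        ids = [f"i{j}" for j in range(n)]
        design = ModelDesign(
            y=rng.normal(size=n), X=np.ones((n, 1)), fixed_names=["mu"],
            Zc=np.ones((n, 1)), coef_names=["ind_0"],
            year_codes=np.full(n, -1), year_levels=[], ind_ids=ids,
            resid_class=np.zeros(n, int), trait_indicator=np.zeros(n, int))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_reml(design, n_starts=1, seed=0)
        assert (not fit.identifiable) or fit.boundary

    def test_sampling_cov_symmetric_psd(self, small_order1_fit):
        cov = small_order1_fit.vc_sampling_cov
        assert cov is not None
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(cov).min() > -1e-8 * max(1.0, np.abs(cov).max())


class TestParameterRecovery:
    def test_order1_g_recovery_and_coverage(self):
        # data simulated from the order-1 model: 300 individuals, ~3 records
        # each; all three G elements are well identified at order 1, so the
        # 50-replicate medians must sit close to truth and the +/-2 SE
        # intervals must cover at close to nominal rate
        from rrnorm import fit_covariate_scale, owl_like_config, simulate_dataset

        G1 = [[0.141, -0.074, 0.10], [-0.074, 0.24, -0.07], [0.10, -0.07, 0.439]]
        il = np.tril_indices(2)
        Gh, SE = [], []
        for r in range(50):
            cfg = owl_like_config(n_individuals=300, mean_records=3.0,
                                  joint_G=G1, seed=60_000 + r)
            rec, _, _ = simulate_dataset(cfg)
            scale = fit_covariate_scale(rec["covariate"].to_numpy())
            design = build_design(rec, None, order=1, scale=scale)
            fit = fit_reml(design, n_starts=1, seed=r)
            Gh.append(fit.varcomps.G[il])
            SE.append(fit.vc_se[:3])
        Gh, SE = np.array(Gh), np.array(SE)
        truth = np.array(G1)[:2, :2][il]
        med = np.median(Gh, axis=0)
        assert np.all(np.abs(med - truth) <= 0.15 * np.abs(truth)), med
        coverage = np.mean(np.abs(Gh - truth) <= 2 * SE)
        assert 0.85 <= coverage <= 0.99, coverage

    def test_se_shrinks_with_sample_size(self):
        # doubling the number of individuals should shrink variance-component
        # SEs roughly like 1/sqrt(n)
        from rrnorm import fit_covariate_scale, owl_like_config, simulate_dataset

        ses = []
        for n in (100, 400):
            cfg = owl_like_config(n_individuals=n, n_years=12,
                                  joint_G=[[0.25, 0.0], [0.0, 0.4]], seed=77)
            rec, _, _ = simulate_dataset(cfg)
            scale = fit_covariate_scale(rec["covariate"].to_numpy())
            design = build_design(rec, None, order=0, scale=scale)
            fit = fit_reml(design, n_starts=1, seed=0)
            ses.append(fit.vc_se[0])
        ratio = ses[0] / ses[1]
        assert 1.4 <= ratio <= 2.9, ratio


class TestLrt:
    @pytest.mark.parametrize("full, reduced, df, chi2", [
        (-295.2, -397.2, 1, 204.0),
        (-264.8, -295.2, 1, 60.8),
    ])
    def test_statistic_from_loglik_pairs(self, full, reduced, df, chi2):
        got, p = lrt(full, reduced, df)
        assert got == pytest.approx(chi2, abs=1e-9)
        assert p < 0.001

    def test_identical_likelihoods(self):
        chi2, p = lrt(-10.0, -10.0, 3)
        assert chi2 == 0.0
        assert p == 1.0

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            chi2, p = lrt(-10.0, -9.0, 1)
        assert chi2 == 0.0 and p == 1.0

    def test_compare_fits_refuses_different_fixed_effects(self, small_dataset):
        d = small_dataset
        a = build_design(d["records"], None, order=0, scale=d["scale"])
        b = build_design(d["records"], None, order=0, scale=d["scale"],
                         age_reference="1")
        fa = fit_reml(a, n_starts=1, seed=0, compute_se=False)
        fb = fit_reml(b, n_starts=1, seed=0, compute_se=False)
        with pytest.raises(ValueError, match="fixed effects"):
            compare_fits(fa, fb, df=1)


class TestBuildDesign:
    def test_coefficient_block_width(self, small_dataset):
        d = small_dataset
        des = build_design(d["records"], None, order=1, scale=d["scale"])
        assert des.q_coef == 2
        des0 = build_design(d["records"], None, order=0, scale=d["scale"])
        assert des0.q_coef == 1
        assert np.allclose(des0.Zc, 1.0)  # incidence of individuals

    def test_bivariate_order2_joint_block_is_4x4(self, small_dataset):
        d = small_dataset
        des = build_design(d["records"], d["fitness"], order=2, scale=d["scale"])
        assert des.q_coef == 4
        assert des.coef_names == ["ind_0", "ind_1", "ind_2", "w_elev"]
        # fitness rows load only on the elevation column and have no residual
        fit_rows = des.trait_indicator == 1
        assert np.allclose(des.Zc[fit_rows, :3], 0.0)
        assert np.allclose(des.Zc[fit_rows, 3], 1.0)
        assert (des.resid_class[fit_rows] == 1).all()
        assert (des.year_codes[fit_rows] == -1).all()

    def test_mismatched_fitness_rejected(self, small_dataset):
        d = small_dataset
        bad = d["fitness"].iloc[:-1]
        with pytest.raises(ValueError, match="one-to-one"):
            build_design(d["records"], bad, order=1, scale=d["scale"])

    def test_negative_order_rejected(self, small_dataset):
        d = small_dataset
        with pytest.raises(ValueError):
            build_design(d["records"], None, order=-1, scale=d["scale"])
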