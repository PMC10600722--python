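import numpy as np
import pytest
from scipy import stats

from triomr.grm import Grm, compute_grm
from triomr.lmm import conditional_f, fit_lmm_reml, reml_loglik
from triomr.simulate import ScenarioConfig, simulate_background, simulate_cohort
from triomr.snps import replicate_panel


def make_design(rng, n, p=3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    return X


@pytest.fixture(scope="module")
def sib_grm():
    panel = replicate_panel(10, seed=31)
    cfg = ScenarioConfig.null(n_families=100, seed=31, sib_fraction=1.0,
                              n_outcomes=1, item_level=False)
    cohort = simulate_cohort(panel, cfg)
    bg = simulate_background(cohort, n_loci=2000, seed=32)
    return compute_grm(bg.G_o, bg.chrom, bg.pos_bp)


def simulate_mixed_outcome(grm, X, beta, sg, se2, rng):
    d, U = np.linalg.eigh(grm.matrix)
    d = np.clip(d, 0, None)
    g = U @ (np.sqrt(sg * d) * rng.standard_normal(len(d)))
    return X @ beta + g + np.sqrt(se2) * rng.standard_normal(X.shape[0])


class TestIdentityGrmPath:
    def test_matches_ols_exactly(self, rng):
        import statsmodels.api as sm
        X = make_design(rng, 300)
        y = X @ [1.0, 0.5, -0.2] + rng.standard_normal(300)
        fit = fit_lmm_reml(y, X, grm=None)
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.beta, ols.params, atol=1e-8)
        assert np.allclose(fit.se, ols.bse, atol=1e-8)
        assert fit.sigma2_g == 0.0

    def test_explicit_identity_matrix_equivalent(self, rng):
        X = make_design(rng, 100)
        y = rng.standard_normal(100)
        eye = Grm(ids=np.arange(100), matrix=np.eye(100), n_loci_used=1)
        a = fit_lmm_reml(y, X, grm=None)
        b = fit_lmm_reml(y, X, grm=eye)
        assert np.allclose(a.beta, b.beta, atol=1e-12)

    def test_zero_genetic_variance_hits_boundary(self, sib_grm, rng):
        X = make_design(rng, len(sib_grm.ids))
        y = X @ [0.3, 1.0, 0.0] + rng.standard_normal(X.shape[0])
        fit = fit_lmm_reml(y, X, sib_grm)
        import statsmodels.api as sm
        ols = sm.OLS(y, X).fit()
        assert fit.sigma2_g < 0.05
        assert np.allclose(fit.beta, ols.params, atol=0.02)


class TestSpectralReml:
    def test_optimum_beats_random_lambda_probes(self, sib_grm, rng):
        n = len(sib_grm.ids)
        X = make_design(rng, n)
        y = simulate_mixed_outcome(sib_grm, X, np.array([1.0, 0.2, -0.4]),
                                   0.5, 0.5, rng)
        fit = fit_lmm_reml(y, X, sib_grm)
        d, U = np.linalg.eigh(sib_grm.matrix)
        d = np.clip(d, 0, None)
        yt, Xt = U.T @ y, U.T @ X
        ll_fit = reml_loglik(fit.sigma2_g, fit.sigma2_e, d, yt, Xt)
        for lam in np.exp(rng.uniform(-8, 4, 50)):
            se2 = max(fit.sigma2_e, 1e-3)
            assert ll_fit >= reml_loglik(lam * se2, se2, d, yt, Xt) - 1e-6

    def test_gls_whitening_reproduces_beta(self, sib_grm, rng):
        n = len(sib_grm.ids)
        X = make_design(rng, n)
        y = simulate_mixed_outcome(sib_grm, X, np.array([0.0, 0.5, 0.5]),
                                   0.4, 0.6, rng)
        fit = fit_lmm_reml(y, X, sib_grm)
        d, U = np.linalg.eigh(sib_grm.matrix)
        d = np.clip(d, 0, None)
        w = np.sqrt(fit.sigma2_g * d + fit.sigma2_e)
        yw = (U.T @ y) / w
        Xw = (U.T @ X) / w[:, None]
        beta_w, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        assert np.allclose(beta_w, fit.beta, atol=1e-8)

    def test_wald_p_uniform_under_null(self):
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(500):
            X = make_design(rng, 200)
            y = rng.standard_normal(200)
            fit = fit_lmm_reml(y, X, grm=None)
            pvals.append(fit.wald_p[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficient_design_names_terms(self, rng):
        X = make_design(rng, 50)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm_reml(rng.standard_normal(50), X,
                         term_names=["i", "a", "b", "a_copy"])

    def test_incomplete_cases_dropped(self, rng):
        X = make_design(rng, 100)
        y = rng.standard_normal(100)
        y[:10] = np.nan
        fit = fit_lmm_reml(y, X, grm=None)
        assert fit.n == 90


class TestConditionalF:
    def test_collinear_instrument_rejected(self, rng):
        x = rng.standard_normal(200)
        with pytest.raises(ValueError, match="collinear"):
            conditional_f(rng.standard_normal(200), x, [x])

    def test_null_instrument_f_near_one(self):
        rng = np.random.default_rng(5)
        fs = [conditional_f(rng.standard_normal(300), rng.standard_normal(300),
                            [rng.standard_normal(300)])
              for _ in range(200)]
        assert 0.7 < np.mean(fs) < 1.4

    def test_partial_f_equals_squared_t(self, rng):
        import statsmodels.api as sm
        n = 500
        z = rng.standard_normal(n)
        x = 0.5 * z + rng.standard_normal(n)
        y = 0.3 * x + 0.2 * z + rng.standard_normal(n)
        f = conditional_f(y, x, [z])
        X = sm.add_constant(np.column_stack([x, z]))
        t = sm.OLS(y, X).fit().tvalues[1]
        assert f == pytest.approx(t ** 2, rel=1e-10)
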