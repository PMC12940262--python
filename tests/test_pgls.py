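import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from canine_lag.pgls import (
    ModelSpec,
    PGLSRegressor,
    TRAIT_SPECS,
    anova_interaction,
    cancer_mortality_rate,
    design_matrix,
    fit_pgls,
    jarque_bera,
    predict,
    transform_response,
)


def random_dataset(rng, n=25, k=3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(size=k)
    y = X @ beta + rng.normal(size=n)
    return y, X


def ols_reference(y, X):
    """Independent OLS oracle (statsmodels)."""
    import statsmodels.api as sm

    return sm.OLS(y, X).fit()


class TestGLSCore:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y, X = random_dataset(rng)
            fit = fit_pgls(y, X, np.eye(len(y)))
            ref = ols_reference(y, X)
            assert np.allclose(fit.coef, ref.params, atol=1e-10)
            assert np.allclose(fit.se, ref.bse, atol=1e-10)
            assert np.allclose(fit.tvalues, ref.tvalues, atol=1e-8)
            assert np.allclose(fit.pvalues, ref.pvalues, atol=1e-8)
            assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)
            assert fit.fvalue == pytest.approx(ref.fvalue, abs=1e-8)

    def test_scalar_covariance_leaves_inference_unchanged(self):
        rng = np.random.default_rng(1)
        y, X = random_dataset(rng)
        base = fit_pgls(y, X, np.eye(len(y)))
        for c in (0.01, 3.7, 2000.0):
            fit = fit_pgls(y, X, c * np.eye(len(y)))
            assert np.allclose(fit.coef, base.coef, atol=1e-10)
            assert np.allclose(fit.tvalues, base.tvalues, atol=1e-8)
            assert fit.r2 == pytest.approx(base.r2, abs=1e-10)
            assert fit.fvalue == pytest.approx(base.fvalue, rel=1e-8)

    def test_lambda_zero_on_ultrametric_tree_equals_ols(self, small_mixed_tree, small_traits):
        spec = TRAIT_SPECS["lifespan"]
        y = transform_response(spec, small_traits)
        X, _ = design_matrix(spec, small_traits)
        est = PGLSRegressor(
            tree=small_mixed_tree, lam=0.0,
            taxon_order=small_traits["breed"].tolist(),
        ).fit(X, y)
        ref = ols_reference(y, X)
        assert np.allclose(est.coef_, ref.params, atol=1e-8)
        assert np.allclose(est.se_, ref.bse, atol=1e-8)

    def test_noiseless_recovery(self, small_mixed_tree):
        from canine_lag.phylogeny import tree_to_covariance

        V = tree_to_covariance(small_mixed_tree).to_numpy()
        rng = np.random.default_rng(2)
        n = len(V)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([2.0, -0.5])
        fit = fit_pgls(X @ beta, X, V)
        assert np.allclose(fit.coef, beta, atol=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_singular_design_rejected(self):
        y = np.arange(6.0)
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="singular"):
            fit_pgls(y, X, np.eye(6))

    def test_non_psd_covariance_rejected(self):
        y = np.arange(4.0)
        X = np.column_stack([np.ones(4), y])
        V = np.eye(4)
        V[0, 1] = V[1, 0] = 2.0  # eigenvalue -1
        with pytest.raises(ValueError, match="positive semi-definite"):
            fit_pgls(y, X, V)

    def test_sklearn_params_roundtrip(self):
        est = PGLSRegressor(lam=0.3, kappa=0.5)
        assert PGLSRegressor(**est.get_params()).get_params() == est.get_params()


class TestDesign:
    def test_dimensions_without_interaction(self, small_traits):
        X, names = design_matrix(TRAIT_SPECS["lifespan"], small_traits)
        assert X.shape == (6, 3)
        assert names == ["intercept", "weight", "ancient"]
        # modern is the reference level
        assert X[small_traits["label"] == "modern", 2].sum() == 0

    def test_interaction_column(self, small_traits):
        X, names = design_matrix(
            ModelSpec("cmr", "cmr", "log", "log", include_interaction=True),
            small_traits,
        )
        assert names[-1] == "weight:ancient"
        assert np.allclose(X[:, 3], X[:, 1] * X[:, 2])

    def test_single_level_factor_rejected(self, small_traits):
        mono = small_traits.assign(label="modern")
        with pytest.raises(ValueError, match="one level"):
            design_matrix(TRAIT_SPECS["lifespan"], mono)

    def test_log_of_nonpositive_names_breed(self, small_traits):
        bad = small_traits.copy()
        bad.loc[0, "weight_kg"] = -1.0
        with pytest.raises(ValueError, match="ancient_1"):
            design_matrix(TRAIT_SPECS["litter"], bad)

    def test_cmr_spec_uses_log_scales(self):
        spec = TRAIT_SPECS["cmr"]
        assert spec.response_transform == "log"
        assert spec.weight_transform == "log"
        assert spec.include_interaction


class TestAnova:
    def test_identical_models_give_zero_f(self, small_traits, small_mixed_tree):
        spec = TRAIT_SPECS["lifespan"]
        y = transform_response(spec, small_traits)
        X, terms = design_matrix(spec, small_traits)
        fit = fit_pgls(y, X, np.eye(6), terms=terms)
        f, df1, df2, p = anova_interaction(fit, fit)
        assert (f, df1, p) == (0.0, 0, 1.0)

    def test_partial_f_matches_brute_force(self):
        # 6-point hand dataset, V = I: F from explicit RSS arithmetic
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        z = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        y = np.array([1.1, 2.3, 2.8, 4.6, 4.9, 6.5])
        X_red = np.column_stack([np.ones(6), x])
        X_full = np.column_stack([np.ones(6), x, z])
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        f_expected = ((rss(X_red) - rss(X_full)) / 1) / (rss(X_full) / 3)
        full = fit_pgls(y, X_full, np.eye(6), terms=["intercept", "x", "z"])
        red = fit_pgls(y, X_red, np.eye(6), terms=["intercept", "x"])
        f, df1, df2, p = anova_interaction(full, red)
        assert (df1, df2) == (1, 3)
        assert f == pytest.approx(f_expected, rel=1e-10)
        assert p == pytest.approx(scipy.stats.f.sf(f_expected, 1, 3), rel=1e-10)

    def test_non_nested_rejected(self):
        y = np.arange(6.0) + 0.1 * np.arange(6.0) ** 2
        A = np.column_stack([np.ones(6), np.arange(6.0)])
        B = np.column_stack([np.ones(6), np.arange(6.0) ** 2])
        fa = fit_pgls(y, A, np.eye(6), terms=["intercept", "x"])
        fb = fit_pgls(y, B, np.eye(6), terms=["intercept", "x2"])
        with pytest.raises(ValueError, match="nested"):
            anova_interaction(fa, fb)


class TestPredict:
    def _fit_with(self, terms, coef, spec):
        from canine_lag.pgls import PGLSFit

        k = len(coef)
        z = np.zeros(k)
        return PGLSFit(terms=terms, coef=np.array(coef), se=z, tvalues=z,
                       pvalues=z, sigma2=0.0, r2=1.0, fvalue=0.0, f_pvalue=1.0,
                       df1=k - 1, df2=0, n=k, loglik=0.0, rss=0.0, tss=0.0,
                       pagel={}, resid=z, phylo_resid=z, spec=spec)

    def test_identity_scale_hand_arithmetic(self):
        spec = ModelSpec("lifespan", "lifespan_yr")
        fit = self._fit_with(["intercept", "weight", "ancient"], [1.0, 2.0, 0.5], spec)
        assert predict(fit, spec, 3.0, "modern") == pytest.approx(7.0)
        assert predict(fit, spec, 3.0, "ancient") == pytest.approx(7.5)

    def test_sqrt_backtransform(self):
        spec = ModelSpec("litter", "litter_size", "sqrt", "log")
        fit = self._fit_with(["intercept", "weight", "ancient"], [2.5, 0.0, 0.0], spec)
        assert predict(fit, spec, 10.0, "modern") == pytest.approx(6.25)

    def test_sqrt_scale_group_difference_is_the_factor_effect(self):
        """The printed litter predictions are self-consistent: the sqrt-scale
        gap between ancient and modern at any weight equals the factor
        coefficient."""
        spec = TRAIT_SPECS["litter"]
        fit = self._fit_with(["intercept", "weight", "ancient"],
                             [1.4651, 0.3435, -0.1778], spec)
        anc = predict(fit, spec, 10.0, "ancient")
        mod = predict(fit, spec, 10.0, "modern")
        assert np.sqrt(anc) - np.sqrt(mod) == pytest.approx(-0.1778, abs=5e-4)
        # published worked example: 4.32 vs 5.09 at 10 kg
        assert np.sqrt(4.32) - np.sqrt(5.09) == pytest.approx(-0.1778, abs=5e-4)

    def test_unknown_level_rejected(self):
        spec = ModelSpec("lifespan", "lifespan_yr")
        fit = self._fit_with(["intercept", "weight"], [1.0, 2.0], spec)
        with pytest.raises(ValueError, match="factor level"):
            predict(fit, spec, 3.0, "medieval")

    def test_noiseless_fit_predicts_inputs_exactly(self, small_traits, small_mixed_tree):
        from canine_lag.pgls import fit_trait_model

        spec = TRAIT_SPECS["lifespan"]
        df = small_traits.copy()
        w = df["weight_kg"].to_numpy()
        ind = (df["label"] == "ancient").to_numpy(float)
        df["lifespan_yr"] = 13.0 - 0.09 * w + 1.3 * ind
        fit = fit_trait_model(df, small_mixed_tree, "lifespan", lam=1.0)
        for _, row in df.iterrows():
            assert predict(fit, spec, row.weight_kg, row.label) == pytest.approx(
                row.lifespan_yr, abs=1e-8
            )


class TestJarqueBera:
    def test_zero_for_symmetric_mesokurtic_vector(self):
        # symmetric, kurtosis exactly 3: +-{1,1,1,c} with c^4 - 18c^2 - 15 = 0
        c = np.sqrt((18 + np.sqrt(324 + 60)) / 2)
        r = np.array([1.0, 1.0, 1.0, c, -1.0, -1.0, -1.0, -c])
        res = jarque_bera(r)
        assert res.jb == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_moment_oracle_and_scipy(self):
        r = (np.arange(1.0, 11.0)) ** 2  # skewed fixed vector
        res = jarque_bera(r)
        n = len(r)
        c = r - r.mean()
        S = np.mean(c**3) / np.mean(c**2) ** 1.5
        K = np.mean(c**4) / np.mean(c**2) ** 2
        assert res.jb == pytest.approx(n / 6 * (S**2 + (K - 3) ** 2 / 4), rel=1e-12)
        sp = scipy.stats.jarque_bera(r)
        assert res.jb == pytest.approx(sp.statistic, rel=1e-10)
        assert res.p == pytest.approx(sp.pvalue, rel=1e-10)

    def test_constant_and_short_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            jarque_bera(np.ones(10))
        with pytest.raises(ValueError, match="at least 8"):
            jarque_bera(np.arange(5.0))

    @settings(max_examples=30, deadline=None)
    @given(loc=st.floats(-50, 50), scale=st.floats(0.01, 100), seed=st.integers(0, 99))
    def test_location_scale_invariance(self, loc, scale, seed):
        r = np.random.default_rng(seed).normal(size=40)
        a = jarque_bera(r)
        b = jarque_bera(loc + scale * r)
        assert b.jb == pytest.approx(a.jb, rel=1e-6, abs=1e-9)


@pytest.mark.parametrize(
    "cancer, diagnosed, expected",
    [(0, 50, 0.0), (50, 50, 1.0), (17, 100, 0.17)],
)
def test_cancer_mortality_rate(cancer, diagnosed, expected):
    assert cancer_mortality_rate(cancer, diagnosed) == expected


def test_cancer_mortality_rate_errors():
    with pytest.raises(ValueError, match="zero diagnosed"):
        cancer_mortality_rate(1, 0)
    with pytest.raises(ValueError):
        cancer_mortality_rate(10, 5)
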