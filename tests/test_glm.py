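"""Gamma log-link GLM core: design construction, IRLS estimates against
independent oracles, residual definitions, Wald inference and AICc."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import paycharge as pc
from paycharge.aggregate import RankDeficiencyError
from paycharge.glm import GammaGLM, ModelSpec, aicc, build_design, star_marker


def _sim_gamma(rng, n, beta, shape=8.0, k_covs=None):
    k = len(beta) - 1 if k_covs is None else k_covs
    X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, k))])
    mu = np.exp(X @ np.asarray(beta))
    return X, rng.gamma(shape, mu / shape)


class TestBuildDesign:
    def test_categorical_encoding(self):
        df = pd.DataFrame({"pcr": [0.2, 0.4, 0.6, 0.3, 0.5],
                           "grp": ["a", "b", "c", "a", "b"],
                           "x": [1.0, 2.0, 0.5, 1.5, 2.5]})
        X, y, names, _ = build_design(ModelSpec("medicare", ["grp", "x"]), df)
        # 3 levels -> 2 dummies, plus intercept and x
        assert names == ["intercept", "grp_b", "grp_c", "x"]
        assert X.shape == (5, 4)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"pcr": [0.2, 0.4, 0.6, 0.3],
                           "flat": [1.0, 1.0, 1.0, 1.0],
                           "x": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(RankDeficiencyError) as err:
            build_design(ModelSpec("medicare", ["flat", "x"]), df)
        assert set(err.value.columns) & {"intercept", "flat"}

    def test_hand_constructed_matrix(self):
        df = pd.DataFrame({"pcr": [0.1, 0.2, 0.3, 0.4, 0.5],
                           "a": [1.0, 0.0, 1.0, 0.0, 1.0],
                           "b": [2.0, 4.0, 6.0, 8.0, 10.0]})
        X, y, names, info = build_design(ModelSpec("medicare", ["a", "b"]), df)
        want = np.array([[1, 1, 2], [1, 0, 4], [1, 1, 6], [1, 0, 8], [1, 1, 10]],
                        dtype=float)
        assert np.array_equal(X, want)
        assert np.array_equal(y, df["pcr"].to_numpy())
        assert info["n_dropped"] == 0

    def test_missing_rows_dropped_and_counted(self):
        df = pd.DataFrame({"pcr": [0.1, 0.2, 0.3, np.nan, 0.5],
                           "x": [1.0, np.nan, 3.0, 4.0, 5.0]})
        X, y, _, info = build_design(ModelSpec("medicare", ["x"]), df)
        assert info["n_dropped"] == 2
        assert len(y) == 3

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("medicare", ["x", "x"])


class TestFit:
    @given(st.lists(st.floats(1e-3, 1e3), min_size=3, max_size=40))
    def test_intercept_only_mean_identity(self, ys):
        y = np.asarray(ys)
        fit = GammaGLM(y, np.ones((len(y), 1))).fit()
        assert fit.fittedvalues[0] == pytest.approx(y.mean(), rel=1e-7)

    def test_grid_search_oracle_12_points(self):
        # brute-force profile likelihood: for fixed shape the gamma MLE in
        # beta maximises -sum(y/mu + log mu), independent of the shape
        rng = np.random.default_rng(4)
        X, y = _sim_gamma(rng, 12, [-0.8, 0.4], shape=6.0)

        def nll(b0, b1):
            mu = np.exp(b0 + b1 * X[:, 1])
            return np.sum(y / mu + np.log(mu))

        b0g, b1g = -0.8, 0.4
        for half_width, step in ((1.0, 0.01), (0.02, 0.0002), (0.0004, 4e-6)):
            b0s = np.arange(b0g - half_width, b0g + half_width, step)
            b1s = np.arange(b1g - half_width, b1g + half_width, step)
            vals = np.array([[nll(a, b) for b in b1s] for a in b0s])
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            b0g, b1g = b0s[i], b1s[j]

        fit = GammaGLM(y, X).fit()
        assert fit.params.iloc[0] == pytest.approx(b0g, abs=5e-4)
        assert fit.params.iloc[1] == pytest.approx(b1g, abs=5e-4)

    def test_agrees_with_reference_implementation(self):
        # independent oracle: statsmodels GLM on 50 random small datasets
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(25, 80))
            k = int(rng.integers(1, 4))
            beta = rng.normal(0, 0.4, k + 1)
            X, y = _sim_gamma(rng, n, beta, shape=5.0)
            ours = GammaGLM(y, X).fit()
            ref = sm.GLM(y, X, family=sm.families.Gamma(
                link=sm.families.links.Log())).fit()
            assert np.allclose(ours.fittedvalues, ref.fittedvalues, atol=1e-4)
            assert np.allclose(ours.params.to_numpy(), ref.params, atol=1e-4)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        X, y = _sim_gamma(rng, 200, [-1.0, 0.3])
        c = 12.5
        Xs = X.copy()
        Xs[:, 1] *= c
        a = GammaGLM(y, X).fit()
        b = GammaGLM(y, Xs).fit()
        assert b.params.iloc[1] == pytest.approx(a.params.iloc[1] / c, rel=1e-6)
        assert np.allclose(a.fittedvalues, b.fittedvalues, rtol=1e-8)
        assert a.deviance == pytest.approx(b.deviance, rel=1e-8)
        assert a.aicc == pytest.approx(b.aicc, rel=1e-8)

    def test_rejects_nonpositive_response(self):
        with pytest.raises(ValueError):
            GammaGLM(np.array([1.0, 0.0, 2.0]), np.ones((3, 1)))

    def test_rejects_saturated(self):
        with pytest.raises(ValueError):
            GammaGLM(np.array([1.0, 2.0]), np.ones((2, 2)))

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(1)
        X, y = _sim_gamma(rng, 100, [-1.0, 0.5])
        with pytest.warns(RuntimeWarning):
            fit = GammaGLM(y, X).fit(max_iter=1)
        assert not fit.converged


class TestResiduals:
    def test_perfect_fit_zero_residuals(self):
        y = np.full(10, 3.7)
        fit = GammaGLM(y, np.ones((10, 1))).fit()
        for kind in ("response", "pearson", "deviance"):
            assert np.allclose(fit.resid(kind), 0.0, atol=1e-10)

    def test_pearson_mean_zero_intercept_only(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(4, 0.1, 60)
        fit = GammaGLM(y, np.ones((60, 1))).fit()
        # the score identity holds to solver tolerance
        assert abs(fit.resid("pearson").mean()) < 1e-6

    def test_deviance_formula(self):
        rng = np.random.default_rng(3)
        X, y = _sim_gamma(rng, 40, [-1.0, 0.2])
        fit = GammaGLM(y, X).fit()
        mu = fit.fittedvalues
        want = np.sign(y - mu) * np.sqrt(2 * ((y - mu) / mu - np.log(y / mu)))
        assert np.allclose(fit.resid("deviance"), want)

    def test_unknown_kind(self):
        fit = GammaGLM(np.array([1.0, 2, 3]), np.ones((3, 1))).fit()
        with pytest.raises(ValueError):
            fit.resid("studentized")


class TestPredict:
    def test_zero_covariates_give_exp_intercept(self):
        rng = np.random.default_rng(5)
        X, y = _sim_gamma(rng, 50, [-0.7, 0.3])
        fit = GammaGLM(y, X).fit()
        row = np.array([[1.0, 0.0]])
        assert fit.predict(row)[0] == pytest.approx(np.exp(fit.params.iloc[0]))

    def test_training_rows_reproduce_fitted(self):
        rng = np.random.default_rng(6)
        X, y = _sim_gamma(rng, 50, [-0.7, 0.3])
        fit = GammaGLM(y, X).fit()
        assert np.allclose(fit.predict(X), fit.fittedvalues)

    def test_intercept_only_two_points(self):
        fit = GammaGLM(np.array([2.0, 8.0]), np.ones((2, 1))).fit()
        assert np.allclose(fit.predict(np.ones((3, 1))), 5.0)

    def test_column_mismatch(self):
        fit = GammaGLM(np.array([1.0, 2, 3]), np.ones((3, 1))).fit()
        with pytest.raises(ValueError):
            fit.predict(np.ones((2, 4)))


class TestInference:
    @pytest.mark.parametrize("p,stars", [
        (1.0, ""), (0.05, ""), (0.049, "*"), (0.01, "*"),
        (0.009, "**"), (0.001, "**"), (0.0009, "***"),
    ])
    def test_star_thresholds_strict(self, p, stars):
        assert star_marker(p) == stars

    def test_zero_coefficient_p_one(self):
        rng = np.random.default_rng(8)
        X, y = _sim_gamma(rng, 100, [-1.0, 0.0])
        fit = GammaGLM(y, X).fit()
        fit.params.iloc[1] = 0.0  # force the exact null value
        tab = fit.wald_table()
        assert tab["p"].iloc[1] == pytest.approx(1.0)
        assert tab["stars"].iloc[1] == ""

    def test_wald_table_contents(self):
        rng = np.random.default_rng(9)
        X, y = _sim_gamma(rng, 300, [-1.0, 0.5])
        tab = GammaGLM(y, X).fit().wald_table()
        assert np.allclose(tab["z"], tab["coef"] / tab["se"])
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()
        assert np.allclose(tab["exp_coef_minus_1"], np.expm1(tab["coef"]))


class TestAICc:
    def test_hand_arithmetic(self):
        # n=20, k=3, loglik=-10 -> 20 + 6 + 24/16 = 27.5
        assert aicc(-10.0, 20, 3) == pytest.approx(27.5)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 4)

    def test_nested_models_deviance_monotone(self):
        rng = np.random.default_rng(10)
        X, y = _sim_gamma(rng, 80, [-1.0, 0.3, -0.2], shape=6.0)
        small = GammaGLM(y, X[:, :2]).fit()
        large = GammaGLM(y, X).fit()
        assert large.deviance <= small.deviance + 1e-10

    def test_results_property_counts_dispersion(self):
        rng = np.random.default_rng(12)
        X, y = _sim_gamma(rng, 50, [-1.0, 0.3])
        fit = GammaGLM(y, X).fit()
        assert fit.aicc == pytest.approx(aicc(fit.loglik, 50, 3))


class TestSerialization:
    def test_json_shape(self, tmp_path):
        rng = np.random.default_rng(13)
        X, y = _sim_gamma(rng, 60, [-1.0, 0.3])
        spec = ModelSpec("medicare", [])
        model = GammaGLM(y, X, exog_names=["intercept", "x"], spec=spec)
        fit = model.fit()
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json
        d = json.loads(path.read_text())
        assert d["payer"] == "medicare"
        assert set(d["coefficients"]) == {"intercept", "x"}
        assert {"coef", "se", "p", "stars"} <= set(d["coefficients"]["x"])
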