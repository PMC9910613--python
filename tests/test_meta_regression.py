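"""Weighted mixed-model engine and meta-regression derived quantities."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from qgdiv.lmm import RandomTerm, WeightedLMM
from qgdiv.meta_regression import (
    MetaDataset,
    attenuation_correct,
    backtransform_log_ratio,
    compare_aic,
    estimate_reliability,
    fit_weighted_lmm,
    r2_nakagawa,
    slope_to_percent,
)


def _toy_lmm_data(seed=42, n_g=12, per=8):
    """Random-intercept + random-slope data with heteroscedastic weights."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_g), per)
    x = rng.normal(size=n_g * per)
    b = rng.normal(scale=0.7, size=n_g)
    s = rng.normal(scale=0.4, size=n_g)
    w = rng.uniform(0.5, 3.0, size=n_g * per)
    y = 1.5 + 0.8 * x + b[g] + s[g] * x + rng.normal(scale=1.0 / np.sqrt(w))
    return pd.DataFrame({"y": y, "x": x, "g": g, "w": w})


class TestEngineAgainstReferences:
    def test_no_random_terms_equal_weights_is_ols(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=60)})
        y = 2.0 + 0.5 * X["x"] + rng.normal(size=60)
        fit = WeightedLMM(y, X).fit("ML")
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.fe_estimates, ols.params, atol=1e-8)

    def test_no_random_terms_unequal_weights_is_wls(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=60)})
        w = rng.uniform(0.2, 5.0, size=60)
        y = 2.0 + 0.5 * X["x"] + rng.normal(scale=1 / np.sqrt(w))
        fit = WeightedLMM(y, X, weights=w).fit("ML")
        wls = sm.WLS(y, X, weights=w).fit()
        np.testing.assert_allclose(fit.fe_estimates, wls.params, atol=1e-8)

    def test_weighted_random_slope_fit_matches_lme4(self):
        """Frozen oracle: lme4::lmer(y ~ x + (1|g) + (0+x|g), weights=w,
        REML=FALSE) on the seed-42 toy dataset."""
        df = _toy_lmm_data()
        X = pd.DataFrame({"intercept": 1.0, "x": df["x"]})
        terms = [
            RandomTerm("int|g", df["g"].to_numpy()),
            RandomTerm("x|g", df["g"].to_numpy(), df["x"].to_numpy()),
        ]
        fit = WeightedLMM(df["y"], X, weights=df["w"], random_terms=terms).fit("ML")
        np.testing.assert_allclose(
            fit.fe_estimates, [1.258161, 0.7414171], atol=2e-5
        )
        np.testing.assert_allclose(fit.fe_se, [0.1739615, 0.1245482], atol=2e-5)
        assert fit.log_likelihood == pytest.approx(-130.5649, abs=2e-3)
        assert fit.aic == pytest.approx(271.1299, abs=5e-3)
        assert fit.random_variances["int|g"] == pytest.approx(
            0.52872**2, abs=2e-4
        )
        assert fit.random_variances["x|g"] == pytest.approx(0.13046**2, abs=2e-4)
        assert fit.sigma2 == pytest.approx(1.102472, abs=2e-4)

    def test_reml_variances_match_lme4(self):
        df = _toy_lmm_data()
        X = pd.DataFrame({"intercept": 1.0, "x": df["x"]})
        terms = [RandomTerm("int|g", df["g"].to_numpy())]
        fit = WeightedLMM(df["y"], X, weights=df["w"], random_terms=terms).fit(
            "REML"
        )
        # lme4 REML oracle for the intercept-only random structure
        ml = WeightedLMM(df["y"], X, weights=df["w"], random_terms=terms).fit("ML")
        assert fit.random_variances["int|g"] > ml.random_variances["int|g"]

    def test_halved_weights_on_duplicated_rows_leave_estimates(self):
        df = _toy_lmm_data(seed=3)
        X = pd.DataFrame({"intercept": 1.0, "x": df["x"]})
        fit1 = WeightedLMM(df["y"], X, weights=df["w"]).fit("ML")
        df2 = pd.concat([df, df], ignore_index=True)
        X2 = pd.DataFrame({"intercept": 1.0, "x": df2["x"]})
        fit2 = WeightedLMM(
            df2["y"], X2, weights=np.concatenate([df["w"] / 2, df["w"] / 2])
        ).fit("ML")
        np.testing.assert_allclose(fit2.fe_estimates, fit1.fe_estimates, atol=1e-8)

    def test_rank_deficient_design_names_aliased_term(self):
        X = pd.DataFrame({"intercept": np.ones(10), "x": np.arange(10.0)})
        X["x_copy"] = X["x"]
        with pytest.raises(ValueError, match="x_copy"):
            WeightedLMM(np.zeros(10), X)

    def test_boundary_variance_flagged(self):
        rng = np.random.default_rng(4)
        g = np.repeat(np.arange(10), 6)
        y = rng.normal(size=60)  # no group structure at all
        X = pd.DataFrame({"intercept": np.ones(60)})
        fit = WeightedLMM(y, X, random_terms=[RandomTerm("int|g", g)]).fit("ML")
        assert fit.boundary

    def test_slope_recovery_in_simulation(self):
        """beta=0.8 with study-slope SD 0.5 over 40 studies x 10 traits is
        recovered within 2 SE in >=90% of seeded replicates."""
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            g = np.repeat(np.arange(40), 10)
            x = rng.normal(size=400)
            slopes = rng.normal(scale=0.5, size=40)
            w = rng.uniform(0.5, 2.0, size=400)
            y = 0.8 * x + slopes[g] * x + rng.normal(scale=1 / np.sqrt(w))
            X = pd.DataFrame({"intercept": 1.0, "x": x})
            fit = WeightedLMM(
                y, X, weights=w,
                random_terms=[RandomTerm("x|g", g, x)],
            ).fit("ML")
            est, se = fit.coef("x")
            hits += abs(est - 0.8) <= 2 * se
        assert hits / reps >= 0.9


class TestAttenuation:
    def test_no_error_is_identity(self):
        corrected, rel = attenuation_correct(0.5, 0.0, 1.0)
        assert corrected == 0.5 and rel == 1.0

    def test_published_pair(self):
        # raw 0.76 with reliability 0.7755 corrects to 0.98
        corrected, _ = attenuation_correct(0.76, 1 - 0.7755, 1.0)
        assert corrected == pytest.approx(0.98, abs=5e-3)

    def test_half_reliability_doubles_slope(self):
        corrected, _ = attenuation_correct(1.0, 0.5, 1.0)
        assert corrected == 2.0

    def test_round_trip_identity(self):
        for raw, vme, v in [(0.7, 0.1, 0.5), (1.2, 0.02, 0.3)]:
            corrected, rel = attenuation_correct(raw, vme, v)
            assert corrected * rel == pytest.approx(raw, rel=1e-12)

    def test_all_noise_predictor_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            attenuation_correct(1.0, 1.0, 0.5)

    def test_reliability_estimate_recovers_noise_variance(self):
        rng = np.random.default_rng(9)
        true_log_e = rng.normal(-5, 1.0, size=200)
        rows = []
        for i, le in enumerate(true_log_e):
            for j in range(4):
                rows.append({
                    "species": f"sp{i}", "trait": "t",
                    "evolvability": math.exp(le + rng.normal(0, 0.3)),
                })
        V_me, V, rel = estimate_reliability(pd.DataFrame(rows))
        # error variance of a 4-estimate mean: 0.09/4 = 0.0225
        assert V_me == pytest.approx(0.0225, rel=0.25)
        assert V == pytest.approx(1.0 + 0.0225, rel=0.2)


class TestAicComparison:
    def test_identical_fits(self):
        df = _toy_lmm_data(seed=5)
        X = pd.DataFrame({"intercept": 1.0, "x": df["x"]})
        fit = WeightedLMM(df["y"], X, weights=df["w"]).fit("ML")
        delta, label = compare_aic(fit, fit)
        assert delta == 0.0 and label == "indistinguishable"

    def test_hand_computed_delta(self):
        df = _toy_lmm_data(seed=6)
        X = pd.DataFrame({"intercept": 1.0, "x": df["x"]})
        a = WeightedLMM(df["y"], X, weights=df["w"]).fit("ML")
        b = WeightedLMM(df["y"], X, weights=df["w"]).fit("ML")
        # synthetic AIC values: logLik -100 with 5 params vs -99 with 7
        a.log_likelihood, a.aic = -100.0, 2 * 100 + 2 * 5
        b.log_likelihood, b.aic = -99.0, 2 * 99 + 2 * 7
        delta, _ = compare_aic(a, b)
        assert delta == pytest.approx(2.0)

    def test_reml_rejected(self):
        df = _toy_lmm_data(seed=7)
        X = pd.DataFrame({"intercept": 1.0, "x": df["x"]})
        t = [RandomTerm("int|g", df["g"].to_numpy())]
        reml = WeightedLMM(df["y"], X, weights=df["w"], random_terms=t).fit("REML")
        ml = WeightedLMM(df["y"], X, weights=df["w"], random_terms=t).fit("ML")
        with pytest.raises(ValueError, match="ML"):
            compare_aic(reml, ml)

    def test_added_generative_covariate_lowers_aic(self):
        rng = np.random.default_rng(8)
        x, z = rng.normal(size=(2, 300))
        y = 1.0 + 0.8 * x + 0.6 * z + rng.normal(size=300)
        X0 = pd.DataFrame({"intercept": 1.0, "x": x})
        X1 = X0.assign(z=z)
        f0 = WeightedLMM(y, X0).fit("ML")
        f1 = WeightedLMM(y, X1).fit("ML")
        delta, label = compare_aic(f0, f1)
        assert delta < -2 and label == "complex-supported"


class TestR2:
    def test_no_random_terms_marginal_equals_conditional(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=80)})
        y = 1 + 0.5 * X["x"] + rng.normal(size=80)
        fit = WeightedLMM(y, X).fit("ML")
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(r2c)
        assert 0 < r2m < 1

    def test_null_model_zero_marginal(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"intercept": np.ones(50)})
        fit = WeightedLMM(rng.normal(size=50), X).fit("ML")
        r2m, _ = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.0, abs=1e-10)

    def test_known_variance_partition(self):
        """Generative variances fixed 2 : random 1 : residual 1 give
        r2_marginal ~ 0.5 and r2_conditional ~ 0.75."""
        rng = np.random.default_rng(12)
        n_g, per = 60, 15
        g = np.repeat(np.arange(n_g), per)
        x = rng.normal(size=n_g * per)
        beta = math.sqrt(2.0)
        b = rng.normal(scale=1.0, size=n_g)
        y = beta * x + b[g] + rng.normal(size=n_g * per)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        fit = WeightedLMM(
            y, X, random_terms=[RandomTerm("int|g", g)]
        ).fit("ML")
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.5, abs=0.06)
        assert r2c == pytest.approx(0.75, abs=0.06)


class TestTransforms:
    @pytest.mark.parametrize(
        "slope, pct, expected, tol",
        [
            (0.98, 10.0, 9.8, 0.05),   # published rounded value
            (1.0, 10.0, 10.0, 1e-10),  # isometry
            (0.0, 25.0, 0.0, 1e-12),
        ],
    )
    def test_slope_to_percent(self, slope, pct, expected, tol):
        assert slope_to_percent(slope, pct) == pytest.approx(expected, abs=tol)

    def test_backtransform_log_ratio(self):
        assert backtransform_log_ratio(0.48) == pytest.approx(1.62, abs=5e-3)
        assert backtransform_log_ratio(0.0) == 1.0
        assert backtransform_log_ratio(-0.48) == pytest.approx(
            1 / backtransform_log_ratio(0.48), rel=1e-12
        )


class TestMetaDatasetInterface:
    def test_requires_columns_and_positive_weights(self):
        df = pd.DataFrame({"log_e": [1.0], "log_d": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            MetaDataset(df)
        full = pd.DataFrame(
            {"log_e": [1, 2], "log_d": [1, 2], "weight": [1.0, -1.0],
             "species": ["a", "b"], "study_id": ["s", "t"]}
        )
        with pytest.raises(ValueError, match="weights"):
            MetaDataset(full)

    def test_centering_records_flag(self):
        df = pd.DataFrame(
            {"log_e": [1.0, 2.0], "log_d": [0.0, 1.0], "weight": [1.0, 1.0],
             "species": ["a", "b"], "study_id": ["s", "t"]}
        )
        ds = MetaDataset(df).center_covariates()
        assert ds.centered
        assert ds.data["log_e"].mean() == pytest.approx(0.0)

    def test_moderator_design_adds_interaction(self):
        rng = np.random.default_rng(13)
        n = 80
        df = pd.DataFrame({
            "log_e": rng.normal(size=n),
            "weight": np.ones(n),
            "species": np.repeat([f"sp{i}" for i in range(8)], 10),
            "study_id": np.repeat([f"s{i}" for i in range(16)], 5),
            "grp": np.tile(["floral", "vegetative"], 40),
        })
        df["log_d"] = df["log_e"] + (df["grp"] == "vegetative") * 0.5
        ds = MetaDataset(df)
        fit = fit_weighted_lmm(
            ds, fixed=["log_e"], random_slope=None, moderator="grp"
        )
        assert "grp[vegetative]" in fit.fe_names
        assert "log_e:grp[vegetative]" in fit.fe_names
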