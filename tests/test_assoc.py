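import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grslens.assoc import (
    GRS_COLUMNS, ModelSpec, delta_r2, fit_model, joint_noncorresponding_test,
    moderation_test, nagelkerke_r2, nested_f_test, outcome_panel,
)
from grslens.errors import FitError, ValidationError
from .conftest import make_assoc_frame
from .oracles import logistic_newton, ols_normal_equations


def linear_frame(rng, n=80, noise=1.0):
    age = rng.uniform(45, 84, n)
    sex = rng.integers(0, 2, n)
    g = rng.normal(0, 1, n)
    y = 3.0 + 0.2 * age - 0.001 * age ** 2 - 2.0 * sex + 1.5 * g \
        + noise * rng.normal(size=n)
    return pd.DataFrame({"age": age, "sex": sex, "HDL_GRS": g, "HDL": y})


class TestFitModel:
    def test_exact_fit_r2_one(self, rng):
        df = linear_frame(rng, noise=0.0)
        res = fit_model(ModelSpec("HDL", ["HDL_GRS"]), df)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            df = linear_frame(rng, n=40)
            res = fit_model(ModelSpec("HDL", ["HDL_GRS"]), df)
            X = np.column_stack([np.ones(len(df)), df.age, df.age ** 2,
                                 df.sex, df.HDL_GRS])
            beta, r2 = ols_normal_equations(X, df.HDL.to_numpy())
            np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)
            assert res.r2 == pytest.approx(r2, abs=1e-8)

    def test_duplicate_column_collinearity_named(self, rng):
        df = linear_frame(rng)
        df["HDL_GRS_copy"] = df["HDL_GRS"]
        with pytest.raises(FitError, match="HDL_GRS_copy"):
            fit_model(ModelSpec("HDL", ["HDL_GRS", "HDL_GRS_copy"]), df)

    def test_null_predictor_coefficient_near_zero(self, rng):
        hits = 0
        for rep in range(100):
            df = linear_frame(rng, n=500)
            df["noise_grs"] = rng.normal(size=len(df))
            res = fit_model(ModelSpec("HDL", ["noise_grs"]), df)
            if abs(res.params["noise_grs"]) < 3 * res.bse["noise_grs"]:
                hits += 1
        assert hits >= 95

    def test_tg_log_transform_applied(self, rng):
        df = linear_frame(rng)
        df["TG"] = np.exp(0.01 * df["age"] + 0.3 * df["HDL_GRS"])
        res = fit_model(ModelSpec("TG", ["HDL_GRS"]), df)
        assert res.params["HDL_GRS"] == pytest.approx(0.3, abs=1e-8)

    def test_logistic_matches_newton_oracle(self, rng):
        for _ in range(10):
            n = 300
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(-0.3 + 0.8 * x)))
            y = (rng.random(n) < p).astype(float)
            df = pd.DataFrame({"x": x, "hypertension": y})
            spec = ModelSpec("hypertension", ["x"], family="logistic",
                             covariates=())
            res = fit_model(spec, df.assign(age=50.0, sex=0))
            X = np.column_stack([np.ones(n), x])
            beta, ll = logistic_newton(X, y)
            np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-6)
            assert res.loglik == pytest.approx(ll, abs=1e-6)

    def test_logistic_single_class_rejected(self, rng):
        df = linear_frame(rng).assign(hypertension=0.0)
        with pytest.raises(FitError, match="both classes"):
            fit_model(ModelSpec("hypertension", ["HDL_GRS"],
                                family="logistic"), df)


class TestDeltaR2:
    def test_grs_collinear_with_covariates_gives_zero(self, rng):
        df = linear_frame(rng)
        df["HDL_GRS"] = 1.0 + 2.0 * df["age"] - 0.5 * df["sex"]
        r = delta_r2("HDL", "HDL_GRS", df, n_boot=100, seed=0)
        assert r.delta_r2 == pytest.approx(0.0, abs=1e-12)

    def test_f_p_equals_squared_t_p(self, rng):
        df = linear_frame(rng, n=200)
        r = delta_r2("HDL", "HDL_GRS", df, n_boot=100, seed=0)
        res = fit_model(ModelSpec("HDL", ["HDL_GRS"]), df)
        assert r.p == pytest.approx(res.pvalues["HDL_GRS"], abs=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        df = linear_frame(rng, n=150)
        a = delta_r2("HDL", "HDL_GRS", df, n_boot=100, seed=5)
        df2 = df.assign(HDL_GRS=3.7 * df["HDL_GRS"] - 11.0)
        b = delta_r2("HDL", "HDL_GRS", df2, n_boot=100, seed=5)
        assert a.delta_r2 == pytest.approx(b.delta_r2, abs=1e-12)
        assert a.ci_lower == pytest.approx(b.ci_lower, abs=1e-12)

    def test_recovery_of_configured_delta(self):
        hits = 0
        for rep in range(40):
            df = make_assoc_frame(2000, 0.05, seed=100 + rep, slope=8.0)
            r = delta_r2("HDL", "HDL_GRS", df, n_boot=100, seed=rep)
            if abs(r.delta_r2 - 0.05) <= 0.015:
                hits += 1
        assert hits >= 36

    def test_ci_brackets_point_estimate(self, rng):
        df = linear_frame(rng, n=300)
        r = delta_r2("HDL", "HDL_GRS", df, n_boot=400, seed=1)
        assert r.ci_lower <= r.delta_r2 <= r.ci_upper


class TestModeration:
    @staticmethod
    def two_pop_frame(n_per, slopes, seed, noise_sd=10.0):
        rng = np.random.default_rng(seed)
        frames = []
        for k, slope in enumerate(slopes):
            age = rng.uniform(45, 84, n_per)
            sex = rng.integers(0, 2, n_per)
            g = rng.normal(0.5, 0.25, n_per)
            y = 50.0 + 0.1 * age - 5.0 * sex + slope * g \
                + rng.normal(0, noise_sd, n_per)
            frames.append(pd.DataFrame({
                "age": age, "sex": sex, "HDL_GRS": g, "HDL": y,
                "population": f"P{k}"}))
        return pd.concat(frames, ignore_index=True)

    def test_detects_slope_difference(self):
        df = self.two_pop_frame(1000, (10.0, 2.0), seed=0)
        assert moderation_test("HDL", "HDL_GRS", df).p < 0.001

    def test_equal_slopes_not_rejected_on_average(self):
        rejections = sum(
            moderation_test("HDL", "HDL_GRS",
                            self.two_pop_frame(300, (5.0, 5.0), seed=s)).p < 0.05
            for s in range(100))
        assert rejections <= 12

    def test_df1_is_k_minus_one(self):
        df = self.two_pop_frame(100, (5.0, 5.0, 5.0), seed=1)
        assert moderation_test("HDL", "HDL_GRS", df).df1 == 2

    def test_single_population_errors(self):
        df = self.two_pop_frame(100, (5.0,), seed=1)
        with pytest.raises(ValidationError, match="2 populations"):
            moderation_test("HDL", "HDL_GRS", df)


def four_grs_frame(rng, n=400, betas=(5.0, 0.0, 0.0, 0.0), noise_sd=8.0):
    age = rng.uniform(45, 84, n)
    sex = rng.integers(0, 2, n)
    G = rng.normal(0.5, 0.25, size=(n, 4))
    y = 50.0 + 0.1 * age - 5.0 * sex + G @ np.asarray(betas) \
        + rng.normal(0, noise_sd, n)
    df = pd.DataFrame(G, columns=list(GRS_COLUMNS))
    return df.assign(age=age, sex=sex, HDL=y)


class TestJointTest:
    def test_df1_three_and_power_under_real_effect(self, rng):
        hits = 0
        for rep in range(20):
            df = four_grs_frame(rng, n=2000, betas=(5.0, 3.2, 0.0, 0.0))
            test, coefs = joint_noncorresponding_test("HDL", df)
            assert test.df1 == 3
            hits += test.p < 0.05
        assert hits >= 18

    def test_null_calibration(self, rng):
        rejections = 0
        for rep in range(200):
            df = four_grs_frame(rng, n=300, betas=(5.0, 0.0, 0.0, 0.0))
            test, _ = joint_noncorresponding_test("HDL", df)
            rejections += test.p < 0.05
        assert 2 <= rejections <= 22  # ~binomial(200, 0.05)

    def test_zero_variance_other_scores_error(self, rng):
        df = four_grs_frame(rng)
        for c in GRS_COLUMNS[1:]:
            df[c] = 0.0
        with pytest.raises(FitError):
            joint_noncorresponding_test("HDL", df)

    def test_coefficient_table_has_all_scores(self, rng):
        _, coefs = joint_noncorresponding_test("HDL", four_grs_frame(rng))
        assert list(coefs["grs"]) == list(GRS_COLUMNS)


class TestNagelkerke:
    def test_no_improvement_is_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == 0.0

    def test_formula_oracle(self):
        ll0, ll1, n = 100 * np.log(0.5), -40.0, 100
        want = (1 - np.exp(2 * (ll0 - ll1) / n)) / (1 - np.exp(2 * ll0 / n))
        assert nagelkerke_r2(ll0, ll1, n) == pytest.approx(want, rel=1e-12)

    def test_monotone_in_full_loglik(self):
        ll0 = 80 * np.log(0.5)
        vals = [nagelkerke_r2(ll0, ll1, 80) for ll1 in (-55.0, -45.0, -35.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValidationError):
            nagelkerke_r2(0.0, 0.0, 10)


class TestOutcomePanel:
    def test_single_class_population_undefined_not_crash(self, rng):
        df = four_grs_frame(rng, n=120)
        df["population"] = "P"
        df["T2D"] = 0
        out = outcome_panel(df, ["T2D"])
        assert np.isnan(out.iloc[0]["delta_r2"])

    def test_null_continuous_outcome_near_zero(self, rng):
        df = four_grs_frame(rng, n=800, betas=(0, 0, 0, 0))
        df["population"] = "P"
        df["BMI"] = 27 + rng.normal(0, 4, len(df))
        out = outcome_panel(df, ["BMI"])
        assert out.iloc[0]["delta_r2"] < 0.03

    def test_logistic_effect_detected(self, rng):
        df = four_grs_frame(rng, n=2000)
        df["population"] = "P"
        eta = -0.5 + 1.6 * (df["TG_GRS"] - 0.5) / 0.25 * 0.405  # OR 1.5 per SD
        df["metabolic_syndrome"] = (rng.random(len(df))
                                    < 1 / (1 + np.exp(-eta))).astype(int)
        out = outcome_panel(df, ["metabolic_syndrome"])
        row = out.iloc[0]
        assert row["family"] == "logistic"
        assert row["delta_r2"] > 0 and row["p"] < 0.05


def test_nested_f_identity_with_t():
    # df1=1 nested F equals the square of the added coefficient's t
    rng = np.random.default_rng(3)
    df = linear_frame(rng, n=150)
    full = fit_model(ModelSpec("HDL", ["HDL_GRS"]), df)
    red = fit_model(ModelSpec("HDL", []), df)
    test = nested_f_test(red.r2, full.r2, 1, full.df_resid)
    t = full.params["HDL_GRS"] / full.bse["HDL_GRS"]
    assert test.statistic == pytest.approx(t ** 2, rel=1e-10)
    assert test.p == pytest.approx(2 * stats.t.sf(abs(t), full.df_resid),
                                   rel=1e-10)
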