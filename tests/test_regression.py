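"""OLS fitting, fit metrics and PRESS leave-one-out cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from wlaqfit import (
    ModelSpec,
    cohort_frame,
    default_cohort_spec,
    fit_model_family,
    fit_ols,
    generate_cohort,
    get_model,
    percent_see,
    press,
)

BMI_PA = ModelSpec("bmi+pa", ("age", "sex", "bmi", "pa_score"))


def brute_force_press(data: pd.DataFrame, spec: ModelSpec) -> float:
    """Literal leave-one-out refits — the oracle for the leverage identity."""
    total = 0.0
    for i in range(len(data)):
        train = data.drop(data.index[i])
        fit = fit_ols(train, spec)
        pred = fit.predict(data.iloc[[i]])[0]
        total += (data["vo2max"].iloc[i] - pred) ** 2
    return total


def random_cohort_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Small ad-hoc regression problems, deliberately un-calibrated."""
    return pd.DataFrame(
        {
            "age": rng.uniform(30, 60, n),
            "sex": rng.integers(0, 2, n),
            "bmi": rng.uniform(18, 32, n),
            "wg": rng.uniform(60, 110, n),
            "pct_fat": rng.uniform(10, 45, n),
            "pa_score": rng.integers(0, 45, n),
            "total_sitting": rng.uniform(300, 1400, n),
            "vo2max": rng.uniform(20, 60, n),
        }
    )


class TestFitOLS:
    def test_noiseless_cohort_recovers_published_coefficients(self, noiseless_cohort):
        fit = fit_ols(cohort_frame(noiseless_cohort), BMI_PA)
        m = get_model("bmi+pa")
        assert fit.intercept == pytest.approx(m.intercept, abs=1e-6)
        assert fit.coef["age"] == pytest.approx(m.age, abs=1e-6)
        assert fit.coef["sex"] == pytest.approx(m.sex, abs=1e-6)
        assert fit.coef["bmi"] == pytest.approx(m.body_fat, abs=1e-6)
        assert fit.coef["pa_score"] == pytest.approx(m.pa_score, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.see == pytest.approx(0.0, abs=1e-6)

    def test_exact_line_through_three_points(self):
        data = pd.DataFrame(
            {"age": [0.0, 1.0, 2.0], "vo2max": [0.0, 1.0, 2.0]}
        ).assign(sex=0, bmi=20, wg=80, pct_fat=25, pa_score=0, total_sitting=0)
        fit = fit_ols(data, ModelSpec("line", ("age",)))
        assert fit.coef["age"] == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0) and fit.see == pytest.approx(0.0, abs=1e-12)

    def test_constant_outcome_reports_r2_zero_with_warning(self, rng):
        data = random_cohort_frame(rng, 30)
        data["vo2max"] = 40.0
        with pytest.warns(UserWarning, match="constant outcome"):
            fit = fit_ols(data, BMI_PA)
        assert fit.r2 == 0.0 and fit.adj_r2 == 0.0
        assert all(abs(b) < 1e-10 for b in fit.coef.values())

    def test_matches_direct_sse_minimizer(self, rng):
        data = random_cohort_frame(rng, 40)
        spec = ModelSpec("m", ("age", "bmi"))
        fit = fit_ols(data, spec)
        y = data["vo2max"].to_numpy()
        X = np.column_stack([np.ones(len(data)), data["age"], data["bmi"]])
        sse = lambda b: float(((y - X @ b) ** 2).sum())
        res = optimize.minimize(sse, x0=np.zeros(3), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert np.allclose([fit.intercept, fit.coef["age"], fit.coef["bmi"]],
                           res.x, rtol=1e-5, atol=1e-5)

    def test_residuals_sum_to_zero_and_adj_r2_below_r2(self, noisy_cohort):
        fit = fit_ols(cohort_frame(noisy_cohort), BMI_PA)
        assert abs(fit.residuals.sum()) < 1e-7
        assert fit.adj_r2 <= fit.r2 <= 1.0

    def test_adding_a_predictor_never_decreases_r2(self, noisy_cohort):
        df = cohort_frame(noisy_cohort)
        base = fit_ols(df, ModelSpec("b", ("age", "sex", "bmi")))
        bigger = fit_ols(df, ModelSpec("b2", ("age", "sex", "bmi", "total_sitting")))
        assert bigger.r2 >= base.r2

    def test_collinear_design_refused(self, rng):
        data = random_cohort_frame(rng, 30)
        data["wg"] = 2.0 * data["bmi"] + 5.0
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(data, ModelSpec("m", ("bmi", "wg")))

    def test_too_few_rows_refused(self, rng):
        data = random_cohort_frame(rng, 5)
        with pytest.raises(ValueError, match="cannot identify"):
            fit_ols(data, BMI_PA)

    def test_unbiased_coefficient_recovery_over_replicates(self):
        # mean of estimates over stochastic refits at the study's n and noise
        m = get_model("bmi+pa")
        rng = np.random.default_rng(77)
        intercepts, pa_coefs = [], []
        for _ in range(60):
            seed = int(rng.integers(2**31))
            cohort = generate_cohort(default_cohort_spec(n=198, seed=seed))
            fit = fit_ols(cohort_frame(cohort), BMI_PA)
            intercepts.append(fit.intercept)
            pa_coefs.append(fit.coef["pa_score"])
        k = len(intercepts)
        assert np.mean(intercepts) == pytest.approx(
            m.intercept, abs=4 * np.std(intercepts, ddof=1) / np.sqrt(k)
        )
        assert np.mean(pa_coefs) == pytest.approx(
            m.pa_score, abs=4 * np.std(pa_coefs, ddof=1) / np.sqrt(k)
        )


class TestPercentSEE:
    @pytest.mark.parametrize(
        "see, mean, printed",
        [
            (4.29, 38.39, 11.2),  # pooled cohort mean (93·35.0 + 105·41.4)/198
            (4.13, 38.39, 10.8),
            (0.0, 38.39, 0.0),
        ],
    )
    def test_matches_printed_rounding(self, see, mean, printed):
        assert round(percent_see(see, mean), 1) == printed

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_see(4.0, 0.0)


class TestPress:
    def test_leverage_identity_equals_brute_force(self):
        rng = np.random.default_rng(123)
        specs = [
            ModelSpec("a", ("age",)),
            ModelSpec("ab", ("age", "bmi")),
            BMI_PA,
        ]
        for trial in range(20):
            n = int(rng.integers(12, 51))
            data = random_cohort_frame(rng, n)
            spec = specs[trial % len(specs)]
            fast = press(data, spec)
            slow = brute_force_press(data, spec)
            assert fast.press_statistic == pytest.approx(slow, rel=1e-10)
            assert fast.r2p <= fit_ols(data, spec).r2 + 1e-12

    def test_interpolated_data_has_zero_press(self):
        data = pd.DataFrame({"age": np.arange(10.0), "vo2max": 2 * np.arange(10.0) + 5}).assign(
            sex=0, bmi=20, wg=80, pct_fat=25, pa_score=0, total_sitting=0
        )
        res = press(data, ModelSpec("line", ("age",)))
        assert res.press_statistic == pytest.approx(0.0, abs=1e-18)
        assert res.r2p == pytest.approx(1.0)

    def test_press_exceeds_sse(self, noisy_cohort):
        df = cohort_frame(noisy_cohort)
        fit = fit_ols(df, BMI_PA)
        cv = press(df, BMI_PA)
        sse = float((fit.residuals**2).sum())
        assert cv.press_statistic >= sse
        assert cv.seep >= np.sqrt(sse / fit.n)

    def test_self_determined_point_is_an_error(self):
        # a lone point at an extreme x has leverage 1 when p+1 = distinct x's
        data = pd.DataFrame({"age": [0.0, 0.0, 1.0], "vo2max": [1.0, 2.0, 5.0]}).assign(
            sex=0, bmi=20, wg=80, pct_fat=25, pa_score=0, total_sitting=0
        )
        with pytest.raises(ValueError, match="leverage"):
            press(data, ModelSpec("line", ("age",)))


class TestModelFamily:
    def test_grid_layout_and_pa_gain(self, noisy_cohort):
        grid = fit_model_family(cohort_frame(noisy_cohort))
        assert list(grid.index) == ["bmi", "bmi+pa", "wg", "wg+pa", "fat", "fat+pa"]
        # PA score genuinely explains variance in the generating model
        assert grid.loc["bmi+pa", "adj_r2_gain"] > 0
        # without-PA rows have no PA coefficient
        assert np.isnan(grid.loc["bmi", "pa_score"])
        assert grid.loc["bmi+pa", "adj_r2"] > grid.loc["bmi", "adj_r2"]

    def test_minimum_degrees_of_freedom(self, rng):
        data = random_cohort_frame(rng, 6)  # n = p + 2 for the largest model
        data["sex"] = [0, 1, 0, 1, 0, 1]  # both sexes present: full-rank design
        grid = fit_model_family(data)
        assert np.isfinite(grid["see"]).all()

    def test_see_recovers_generating_residual_sd(self):
        cohort = generate_cohort(default_cohort_spec(n=5000, seed=31))
        fit = fit_ols(cohort_frame(cohort), BMI_PA)
        assert fit.see == pytest.approx(4.29, rel=0.02)
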