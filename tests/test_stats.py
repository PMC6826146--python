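import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopid.simulate import CohortEffects, simulate_cohort
from mitopid.stats import (
    SeparationError,
    fit_burden_ancova,
    fit_heteroplasmy_logistic,
    ln1p_inverse,
    ln1p_transform,
    select_covariates,
    univariate_battery,
)


class TestLn1pTransform:
    def test_zero_maps_to_zero(self):
        assert ln1p_transform(0.0) == 0.0

    def test_analytic_anchor(self):
        assert ln1p_transform(np.e - 1) == pytest.approx(1.0, rel=1e-12)

    def test_inverse_of_042(self):
        assert ln1p_inverse(0.42) == pytest.approx(0.5219616, rel=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ln1p_transform(-0.5)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_machine_precision(self, x):
        assert ln1p_inverse(ln1p_transform(x)) == pytest.approx(x, rel=1e-12, abs=1e-12)


class TestUnivariateBattery:
    def test_monotone_burden_in_cd4_nadir_gives_spearman_one(self):
        df = pd.DataFrame(
            {
                "cd4_nadir": np.arange(30, dtype=float),
                "burden_t": np.arange(30, dtype=float) ** 2,
            }
        )
        table = univariate_battery(df, outcome="burden_t")
        row = table.set_index("variable").loc["cd4_nadir"]
        assert row["test"] == "spearman"
        assert row["statistic"] == pytest.approx(1.0)

    def test_identical_groups_sit_at_null_centre(self):
        values = list(np.linspace(0, 1, 10))
        df = pd.DataFrame(
            {"hiv3": ["negative"] * 10 + ["positive_low_peak"] * 10,
             "burden_t": values + values}
        )
        table = univariate_battery(df, outcome="burden_t")
        row = table.set_index("variable").loc["hiv3"]
        assert row["p"] == pytest.approx(1.0)

    def test_age_uses_linear_regression_and_detects_effect(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(2, 72, 200)
        df = pd.DataFrame({"age": age, "burden_t": 0.01 * age + rng.normal(0, 0.1, 200)})
        table = univariate_battery(df, outcome="burden_t")
        row = table.set_index("variable").loc["age"]
        assert row["test"] == "linear_regression"
        assert row["p"] < 1e-6

    def test_all_missing_variable_skipped(self, caplog):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0], "bmi_log": np.nan,
                           "burden_t": [0.1, 0.2, 0.3]})
        with caplog.at_level("WARNING"):
            table = univariate_battery(df, outcome="burden_t")
        assert "bmi_log" not in set(table["variable"])


class TestBurdenAncova:
    def test_zero_noise_recovers_exact_coefficients(self):
        df, _ = simulate_cohort(
            n=300,
            effects=CohortEffects(
                burden_intercept=0.5, beta_age=0.01, beta_smoking=0.2,
                beta_hiv_high=0.3, noise_sd=0.0,
            ),
            seed=42,
        )
        fit = fit_burden_ancova(df)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.params["age"] == pytest.approx(0.01, rel=1e-8)
        assert fit.params["C(smoking, Treatment('never'))[T.current]"] == pytest.approx(
            0.2, rel=1e-8
        )

    def test_collapsed_hiv_factor_equals_two_term_model(self):
        df, _ = simulate_cohort(n=250, seed=7)
        df["hiv3"] = "negative"
        full = fit_burden_ancova(df)
        reduced = fit_burden_ancova(
            df, formula="burden_t ~ age + C(smoking, Treatment('never'))"
        )
        assert full.params["age"] == pytest.approx(reduced.params["age"], rel=1e-10)

    def test_guard_on_tiny_sample(self):
        df, _ = simulate_cohort(n=20, seed=1)
        with pytest.raises(ValueError):
            fit_burden_ancova(df)

    def test_deterministic(self):
        df, _ = simulate_cohort(n=250, seed=9)
        a, b = fit_burden_ancova(df), fit_burden_ancova(df)
        assert a.params == b.params and a.pvalues == b.pvalues


class TestHeteroplasmyLogistic:
    def test_recovers_generative_coefficients_within_ci(self):
        df, _ = simulate_cohort(n=4000, seed=5)
        fit, strata = fit_heteroplasmy_logistic(df)
        for term, truth in (("age", 0.05), ("smoker", 2.0), ("age:smoker", -0.08)):
            lo, hi = fit.conf_int[term]
            assert lo <= truth <= hi, f"{term}: truth {truth} outside [{lo}, {hi}]"
        assert 0 < fit.r2 < 1  # Nagelkerke pseudo-R2 bounded

    def test_stratified_age_slopes_have_opposite_signs(self):
        df, _ = simulate_cohort(n=4000, seed=6)
        _, strata = fit_heteroplasmy_logistic(df)
        assert strata["current"].params["age"] < 0
        assert strata["never"].params["age"] > 0

    def test_balanced_null_coefficients_shrink(self):
        rng = np.random.default_rng(13)
        n = 10_000
        df = pd.DataFrame(
            {
                "age": rng.uniform(2, 72, n),
                "smoker": rng.integers(0, 2, n),
                "hiv3": rng.choice(
                    ["negative", "positive_low_peak", "positive_high_peak"], n
                ),
                "heteroplasmy": rng.integers(0, 2, n),
            }
        )
        df["smoking"] = np.where(df["smoker"] == 1, "current", "never")
        fit, _ = fit_heteroplasmy_logistic(df, stratified=False)
        assert abs(fit.params["age"]) < 0.05
        assert abs(fit.params["smoker"]) < 0.5

    def test_single_outcome_class_rejected(self):
        df, _ = simulate_cohort(n=200, seed=2)
        df["heteroplasmy"] = 0
        with pytest.raises(ValueError):
            fit_heteroplasmy_logistic(df)

    @pytest.mark.filterwarnings("ignore")  # statsmodels warns before we raise
    def test_complete_separation_flagged(self):
        n = 200
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "age": np.concatenate([rng.uniform(2, 30, 100), rng.uniform(40, 72, 100)]),
                "smoker": 0,
                "smoking": "never",
                "hiv3": "negative",
            }
        )
        df["heteroplasmy"] = (df["age"] > 35).astype(int)
        with pytest.raises(SeparationError):
            fit_heteroplasmy_logistic(
                df, formula="heteroplasmy ~ age", stratified=False
            )


class TestSelectCovariates:
    def _cohort(self):
        rng = np.random.default_rng(21)
        n = 400
        age = rng.uniform(2, 72, n)
        bmi_log = rng.normal(3.2, 0.2, n)
        noise_var = rng.normal(0, 1, n)
        df = pd.DataFrame(
            {
                "age": age,
                "smoking": rng.choice(["current", "never"], n),
                "hiv3": rng.choice(
                    ["negative", "positive_low_peak", "positive_high_peak"], n
                ),
                "bmi_log": bmi_log,
                "noise_var": noise_var,
                "burden_t": 0.2 + 0.01 * age + 0.5 * bmi_log
                + rng.normal(0, 0.2, n),
            }
        )
        return df

    def test_true_generator_term_added_and_noise_not(self):
        df = self._cohort()
        uni = univariate_battery(
            df,
            outcome="burden_t",
            tests={
                "bmi_log": ("linear_regression", "logit_screen"),
                "noise_var": ("linear_regression", "logit_screen"),
            },
        )
        selected, log_lines = select_covariates(
            uni, df, candidates={"bmi_log": "bmi_log", "noise_var": "noise_var"}
        )
        assert "bmi_log" in selected
        assert "noise_var" not in selected
        assert any("added" in line for line in log_lines)

    def test_high_p_candidate_never_added(self):
        df = self._cohort()
        uni = pd.DataFrame(
            [{"variable": "noise_var", "test": "linear_regression",
              "statistic": 0.0, "p": 0.5, "n": len(df)}]
        )
        selected, log_lines = select_covariates(
            uni, df, candidates={"noise_var": "noise_var"}
        )
        assert selected == []
        assert any("not added" in line for line in log_lines)
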