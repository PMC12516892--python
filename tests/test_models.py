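"""Adjusted-difference estimation, baseline tests and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import costutility as cu
from costutility.models import (
    Adjustment,
    DegenerateModelError,
    build_design,
    fit_cost_model,
    fit_effect_model,
    pool_rubin,
)

from conftest import small_config


def _cost_frame(seed=3, n_per_arm=150):
    cfg = small_config(seed=seed, n_per_arm=n_per_arm, practices=10)
    cfg.missingness = cu.MissingnessConfig.none()
    trial = cu.generate_trial(cfg)
    costs, _ = cu.value_utilization(trial.complete, cu.UnitCostTable.default())
    df = pd.concat([trial.complete, costs], axis=1)
    df["mh_12m"] = df["cost_outpatient_mental_health_w1"] + df["cost_outpatient_mental_health_w2"]
    df["mh_w0"] = df["cost_outpatient_mental_health_w0"]
    df["qaly_eq5d"] = 0.25 * df["eq5d_t0"] + 0.5 * df["eq5d_t1"] + 0.25 * df["eq5d_t2"]
    return df


@pytest.fixture(scope="module")
def cost_frame():
    return _cost_frame()


class TestFitCostModel:
    def test_constant_outcome_gives_zero_difference(self, cost_frame):
        df = cost_frame.copy()
        df["flat"] = 42.0
        fit = fit_cost_model(df, "flat", Adjustment.none(), se_method="none")
        assert fit.difference == 0.0
        assert fit.mean_csc == fit.mean_tau == 42.0

    def test_all_zero_outcome_degenerate(self, cost_frame):
        df = cost_frame.copy()
        df["zero"] = 0.0
        with pytest.raises(DegenerateModelError):
            fit_cost_model(df, "zero", Adjustment.none(), se_method="none")

    def test_recycled_means_equal_raw_means_without_covariates(self, cost_frame):
        """With no covariates the adjusted means reproduce raw arm means."""
        raw = cost_frame.groupby("arm")["mh_12m"].mean()
        fit = fit_cost_model(cost_frame, "mh_12m", Adjustment.none(), se_method="none")
        assert fit.model_kind == "two_part"
        assert fit.mean_csc == pytest.approx(raw["CSC"], rel=1e-9)
        assert fit.mean_tau == pytest.approx(raw["TAU"], rel=1e-9)

    def test_two_part_expected_mean_matches_sample_mean(self):
        """Moment check: on arm-balanced data the blended recycled two-part
        expectation reproduces the overall sample mean."""
        cfg = cu.TrialConfig.null(seed=29, n_per_arm=600)
        trial = cu.generate_trial(cfg)
        costs, _ = cu.value_utilization(trial.complete, cu.UnitCostTable.default())
        df = pd.concat([trial.complete, costs], axis=1)
        df["mh_12m"] = df["cost_outpatient_mental_health_w1"] + df["cost_outpatient_mental_health_w2"]
        df["mh_w0"] = df["cost_outpatient_mental_health_w0"]
        fit = fit_cost_model(df, "mh_12m", Adjustment.standard("mh_w0"), se_method="none")
        weights = df["arm"].value_counts(normalize=True)
        blended = weights["CSC"] * fit.mean_csc + weights["TAU"] * fit.mean_tau
        assert blended == pytest.approx(df["mh_12m"].mean(), rel=0.01)

    def test_gamma_branch_on_dense_outcome(self, cost_frame):
        fit = fit_cost_model(cost_frame, "cost_outpatient_somatic_w1", Adjustment.none(),
                             se_method="none", zero_threshold=0.5)
        assert fit.model_kind == "gamma_glm"

    def test_null_effect_recovered(self):
        """Balanced arms with no effect: adjusted difference within 3 SEs of 0."""
        cfg = cu.TrialConfig.null(seed=17, n_per_arm=250)
        trial = cu.generate_trial(cfg)
        costs, _ = cu.value_utilization(trial.complete, cu.UnitCostTable.default())
        df = pd.concat([trial.complete, costs], axis=1)
        df["y"] = df["cost_outpatient_mental_health_w1"] + df["cost_outpatient_mental_health_w2"]
        df["base"] = df["cost_outpatient_mental_health_w0"]
        fit = fit_cost_model(df, "y", Adjustment.standard("base"))
        assert abs(fit.difference) < 3 * fit.se


class TestFitEffectModel:
    def test_constant_outcome(self, cost_frame):
        df = cost_frame.copy()
        df["flat"] = 0.5
        fit = fit_effect_model(df, "flat", Adjustment.none(), se_method="none")
        assert fit.difference == 0.0

    def test_linear_branch_matches_ols(self, cost_frame):
        """Linear recycled difference equals the OLS arm coefficient."""
        df = cost_frame.copy()
        df["shifted"] = df["qaly_eq5d"] - 1.0  # force non-positive values -> linear
        fit = fit_effect_model(df, "shifted", Adjustment.standard("eq5d_t0"), se_method="analytic")
        assert fit.model_kind == "linear"
        design = build_design(df, Adjustment.standard("eq5d_t0"))
        ols = sm.OLS(df["shifted"].to_numpy(), design.X).fit()
        assert fit.difference == pytest.approx(ols.params[design.arm_index], abs=1e-10)

    def test_binary_outcome_uses_logistic(self, cost_frame):
        df = cost_frame.copy()
        df["resp"] = (df["qaly_eq5d"] > df["qaly_eq5d"].median()).astype(float)
        fit = fit_effect_model(df, "resp", Adjustment.none(), se_method="none")
        assert fit.model_kind == "logistic"
        raw = df.groupby("arm")["resp"].mean()
        assert fit.mean_csc == pytest.approx(raw["CSC"], abs=1e-6)

    def test_sandwich_close_to_classical_under_homoskedasticity(self):
        """HC1 and classical OLS SEs agree on clean linear data."""
        rng = np.random.default_rng(12)
        n = 2000
        df = pd.DataFrame(
            {
                "arm": np.where(rng.random(n) < 0.5, "CSC", "TAU"),
                "practice_id": rng.integers(0, 20, n).astype(str),
                "x": rng.normal(size=n),
            }
        )
        df["y"] = 1.0 + 0.5 * (df["arm"] == "CSC") + 0.3 * df["x"] + rng.normal(0, 1, n)
        adj = Adjustment(covariates=("x",))
        design = build_design(df, adj)
        robust = sm.OLS(df["y"], design.X).fit(cov_type="HC1")
        classical = sm.OLS(df["y"], design.X).fit()
        i = design.arm_index
        assert robust.bse.iloc[i] == pytest.approx(classical.bse.iloc[i], rel=0.1)


class TestBaselineTests:
    def test_identical_arms_give_p_one(self):
        base = pd.DataFrame({"age": [30.0, 40.0, 50.0, 60.0], "sex": ["female", "male"] * 2})
        df = pd.concat(
            [base.assign(arm="CSC", practice_id="a"), base.assign(arm="TAU", practice_id="b")],
            ignore_index=True,
        )
        out = cu.baseline_tests(df, ["age", "sex"]).set_index("variable")
        assert out.loc["age", "p_value"] == pytest.approx(1.0)
        assert out.loc["sex", "p_value"] == pytest.approx(1.0)

    def test_f_equals_t_squared(self, cost_frame):
        """The regression F-statistic equals the two-sample t² on the same data."""
        arm = (cost_frame["arm"] == "CSC").to_numpy(float)
        X = np.column_stack([np.ones(len(arm)), arm])
        res = sm.OLS(cost_frame["age"].to_numpy(), X).fit()
        t, p_t = __import__("scipy").stats.ttest_ind(
            cost_frame.loc[cost_frame["arm"] == "CSC", "age"],
            cost_frame.loc[cost_frame["arm"] == "TAU", "age"],
        )
        assert res.fvalue == pytest.approx(t**2, rel=1e-9)
        assert res.f_pvalue == pytest.approx(p_t, rel=1e-9)

    def test_large_age_gap_detected(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "arm": ["CSC"] * 200 + ["TAU"] * 200,
                "practice_id": "p",
                "age": np.concatenate([rng.normal(35, 5, 200), rng.normal(50, 5, 200)]),
            }
        )
        out = cu.baseline_tests(df, ["age"])
        assert out.loc[0, "p_value"] < 0.001

    def test_single_level_skipped(self):
        df = pd.DataFrame({"arm": ["CSC", "TAU"], "practice_id": "p", "flag": [1, 1]})
        out = cu.baseline_tests(df, ["flag"])
        assert out.loc[0, "test"] == "skipped"


class TestRubinPooling:
    def test_hand_computed_two_imputation_example(self):
        pooled = pool_rubin([1.0, 2.0], [0.25, 0.25])
        assert pooled.estimate == pytest.approx(1.5)
        assert pooled.within_variance == pytest.approx(0.25)
        assert pooled.between_variance == pytest.approx(0.5)
        assert pooled.total_variance == pytest.approx(0.25 + 1.5 * 0.5)

    def test_identical_results_have_zero_between_variance(self):
        pooled = pool_rubin([2.0] * 5, [0.1] * 5, dfcom=100)
        assert pooled.between_variance == 0.0
        assert pooled.total_variance == pytest.approx(0.1)
        assert pooled.estimate == 2.0

    def test_total_at_least_mean_within(self, rng):
        for _ in range(20):
            q = rng.normal(size=6)
            u = rng.uniform(0.1, 1.0, size=6)
            pooled = pool_rubin(q, u)
            assert pooled.total_variance >= u.mean() - 1e-12

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0], [0.1])
        with pytest.raises(ValueError):
            pool_rubin([1.0, 2.0], [0.1])

    def test_pool_fit_results_requires_same_kind(self, cost_frame):
        a = fit_effect_model(cost_frame, "qaly_eq5d", Adjustment.none(), family="linear", se_method="none")
        b = fit_cost_model(cost_frame, "mh_12m", Adjustment.none(), se_method="none")
        with pytest.raises(ValueError, match="mismatched"):
            cu.pool_fit_results([a, b])
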