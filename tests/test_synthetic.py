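"""Generator contracts: determinism, masking, marginals, cluster structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import costutility as cu
from costutility.synthetic import TrialConfigError, from_tidy, maskable_columns, to_tidy

from conftest import small_config


class TestDeterminismAndMasking:
    def test_same_seed_bitwise_identical(self):
        a = cu.generate_trial(small_config(seed=5))
        b = cu.generate_trial(small_config(seed=5))
        assert a.observed.to_csv(index=False) == b.observed.to_csv(index=False)
        assert a.complete.to_csv(index=False) == b.complete.to_csv(index=False)

    def test_different_seed_differs(self):
        a = cu.generate_trial(small_config(seed=5))
        b = cu.generate_trial(small_config(seed=6))
        assert a.observed.to_csv(index=False) != b.observed.to_csv(index=False)

    def test_zero_missingness_config(self, complete_trial):
        assert not complete_trial.observed.isna().any().any()
        assert complete_trial.observed.equals(complete_trial.complete)

    def test_masked_equals_complete_where_observed(self, small_trial):
        obs, comp = small_trial.observed, small_trial.complete
        num = comp.select_dtypes(include=[np.number]).columns
        mask = obs[num].notna()
        assert np.allclose(obs[num].to_numpy()[mask.to_numpy()], comp[num].to_numpy()[mask.to_numpy()])

    def test_missingness_within_binomial_bounds(self):
        """Realized per-variable missingness sits in the binomial band around
        the configured MAR rate (family-wise adjusted across variables)."""
        trial = cu.generate_trial(cu.TrialConfig.default(seed=21))
        obs = trial.observed
        ms = trial.config.missingness
        n = len(obs)
        groups = maskable_columns(obs)
        n_vars = sum(len(cols) for cols in groups.values())
        alpha = 0.01 / n_vars
        for (kind, idx), cols in groups.items():
            rate = (ms.outcome_rates if kind == "outcome" else ms.utilization_rates)[idx]
            lo, hi = stats.binom.ppf([alpha / 2, 1 - alpha / 2], n, rate) / n
            for col in cols:
                assert lo <= obs[col].isna().mean() <= hi, col


class TestStructure:
    def test_arm_assigned_at_practice_level(self, small_trial):
        per_practice = small_trial.observed.groupby("practice_id")["arm"].nunique()
        assert (per_practice == 1).all()

    def test_practice_counts_and_sizes(self):
        trial = cu.generate_trial(cu.TrialConfig.default(seed=2))
        counts = trial.observed.groupby("arm")["practice_id"].nunique()
        assert counts["CSC"] == counts["TAU"] == 20
        assert (trial.observed.groupby("practice_id").size() >= 1).all()
        assert (trial.observed["arm"].value_counts() == pd.Series({"TAU": 308, "CSC": 307})).all()

    def test_instrument_ranges_respected(self, complete_trial):
        df = complete_trial.complete
        bounds = {"eq5d": (-0.661, 1), "eqvas": (0, 100), "sf6d": (0, 1),
                  "phq9": (0, 27), "gad7": (0, 21), "phq15": (0, 30), "audit": (0, 40)}
        for name, (lo, hi) in bounds.items():
            for t in ("t0", "t1", "t2"):
                assert df[f"{name}_{t}"].between(lo, hi).all(), f"{name}_{t}"

    def test_tidy_round_trip(self, small_trial):
        wide = small_trial.observed
        back = from_tidy(to_tidy(wide))
        back = back[wide.columns].sort_values("patient_id").reset_index(drop=True)
        ref = wide.sort_values("patient_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(back, ref, check_dtype=False)

    def test_write_bundle(self, tmp_path, complete_trial):
        complete_trial.write(tmp_path)
        assert (tmp_path / "trial_observed.csv").exists()
        assert (tmp_path / "trial_config.json").exists()


class TestCalibration:
    def test_null_config_has_no_arm_difference(self):
        """With all effects off and large n, true utilities differ by ~0."""
        cfg = cu.TrialConfig.null(seed=31, n_per_arm=5000)
        trial = cu.generate_trial(cfg)
        df = trial.complete
        for col in ("eq5d_t1", "sf6d_t2"):
            g = df.groupby("arm")[col]
            diff = g.mean()["CSC"] - g.mean()["TAU"]
            # the Monte-Carlo SE must respect the practice random effects, so
            # compute it from practice-level means
            prac = df.groupby(["arm", "practice_id"])[col].mean()
            mc_var = sum(
                prac[arm].var(ddof=1) / prac[arm].size for arm in ("CSC", "TAU")
            )
            assert abs(diff) < 3 * np.sqrt(mc_var), col

    def test_baseline_marginals_round_trip(self):
        """Generated female shares sit near the configured Table-1 marginals."""
        trial = cu.generate_trial(cu.TrialConfig.default(seed=41))
        table = cu.summarize_baseline(trial.observed)
        female = table[(table["variable"] == "sex") & (table["level"] == "female")]
        assert abs(female["CSC_value"].iloc[0] - 0.6124) < 0.05
        assert abs(female["TAU_value"].iloc[0] - 0.6656) < 0.05

    def test_injected_cost_effect_is_exact_in_expectation(self):
        """A per-window shift on a quantity moves its unconditional mean by
        that amount (law of large numbers at n=8000/arm)."""
        cfg = cu.TrialConfig.null(seed=51, n_per_arm=8000)
        cfg.arm_quantity_effects = {"outpatient_mental_contacts": 3.5}
        df = cu.generate_trial(cfg).complete
        g = df.groupby("arm")["outpatient_mental_contacts_w1"]
        diff = g.mean()["CSC"] - g.mean()["TAU"]
        mc_se = np.sqrt((g.sem() ** 2).sum())
        assert abs(diff - 3.5) < 3 * mc_se


class TestBaselineSummary:
    def test_all_female_records(self):
        df = pd.DataFrame(
            {
                "arm": ["CSC"] * 10 + ["TAU"] * 10,
                "sex": ["female"] * 20,
                "age": 40.0,
            }
        )
        table = cu.summarize_baseline(df)
        female = table[(table["variable"] == "sex") & (table["level"] == "female")]
        assert female["CSC"].iloc[0] == "10 (100.00%)"
        assert female["TAU"].iloc[0] == "10 (100.00%)"

    def test_empty_category_row_present(self):
        df = pd.DataFrame({"arm": ["CSC", "TAU"], "sex": ["female", "female"], "age": [30.0, 50.0]})
        table = cu.summarize_baseline(df)
        male = table[(table["variable"] == "sex") & (table["level"] == "male")]
        assert male["CSC"].iloc[0] == "0 (0.00%)"

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            cu.summarize_baseline(pd.DataFrame(columns=["arm"]))


class TestConfigValidation:
    def test_bad_probability_names_field(self):
        cfg = small_config()
        cfg.covariates["p_female"]["CSC"] = 1.3
        with pytest.raises(TrialConfigError, match="p_female"):
            cu.generate_trial(cfg)

    def test_bad_gamma_shape_names_field(self):
        cfg = small_config()
        cfg.quantities["rehab_days"].shape = 0.0
        with pytest.raises(TrialConfigError, match="rehab_days"):
            cu.generate_trial(cfg)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=77)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        loaded = cu.TrialConfig.from_yaml(path)
        a = cu.generate_trial(loaded)
        b = cu.generate_trial(cfg)
        assert a.observed.to_csv(index=False) == b.observed.to_csv(index=False)
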