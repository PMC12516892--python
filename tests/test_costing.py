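"""Valuation rules: unit costs, wages, perspectives, winsorization."""

import numpy as np
import pandas as pd
import pytest

import costutility as cu
from costutility.costing import (
    ConfigurationError,
    UnitCostTable,
    WINDOW_CATEGORIES,
    twelve_month_breakdown,
)
from costutility.synthetic import QUANTITY_NAMES


class TestInflation:
    def test_identity_year(self, unit_table):
        assert unit_table.inflate_to_2019(100.0, 2019) == pytest.approx(100.0)

    def test_forced_ratio(self):
        t = UnitCostTable(
            unit_costs={}, medication={}, cpi={2015: 100.0, 2019: 105.0}
        )
        assert t.inflate_to_2019(100.0, 2015) == pytest.approx(105.0)

    def test_round_trip(self, unit_table):
        up = unit_table.inflate_to_2019(123.45, 2015)
        down = up * unit_table.cpi[2015] / unit_table.cpi[2019]
        assert down == pytest.approx(123.45, abs=1e-9)

    def test_missing_year_is_configuration_error(self, unit_table):
        with pytest.raises(ConfigurationError, match="1999"):
            unit_table.inflate_to_2019(10.0, 1999)


def _zero_quantity_frame(n=4):
    cols = {}
    for name in QUANTITY_NAMES:
        for w in ("w0", "w1", "w2"):
            cols[f"{name}_{w}"] = np.zeros(n)
    df = pd.DataFrame(cols)
    for w in ("w0", "w1", "w2"):
        df[f"performance_{w}"] = 10.0  # no presenteeism loss
    return df


class TestValuation:
    def test_all_zero_quantities_cost_nothing(self, unit_table):
        costs, rejects = cu.value_utilization(_zero_quantity_frame(), unit_table)
        assert rejects.empty
        assert (costs.fillna(0) == 0).all().all()

    def test_simple_inpatient_case(self):
        t = UnitCostTable(
            unit_costs={
                "inpatient_day": (500.0, 2019),
                "inpatient_mental_day": (450.0, 2019),
                "rehab_day": (100.0, 2019),
                "outpatient_somatic_contact": (1.0, 2019),
                "outpatient_mental_contact": (1.0, 2019),
                "nonphysician_contact": (1.0, 2019),
                "medical_aid_unit": (1.0, 2019),
                "formal_care_hour": (1.0, 2019),
            },
            medication={},
            cpi={2019: 100.0},
        )
        df = _zero_quantity_frame(1)
        df["inpatient_days_w1"] = 2.0
        costs, _ = cu.value_utilization(df, t)
        assert costs.loc[0, "cost_inpatient_rehab_w1"] == pytest.approx(1000.0)

    def test_fuzzed_records_match_brute_force_oracle(self, unit_table, rng):
        """Category costs equal an independent cell-by-cell recomputation."""
        n = 150
        df = _zero_quantity_frame(n)
        for name in QUANTITY_NAMES:
            for w in ("w0", "w1", "w2"):
                if name == "performance":
                    df[f"{name}_{w}"] = rng.uniform(0, 10, n)
                else:
                    df[f"{name}_{w}"] = rng.gamma(1.0, 3.0, n)
        costs, _ = cu.value_utilization(df, unit_table)
        uc = unit_table.unit_cost_2019
        for i in rng.choice(n, 25, replace=False):
            for w in ("w0", "w1", "w2"):
                expected = (
                    df.loc[i, f"inpatient_days_{w}"] * uc("inpatient_day")
                    + df.loc[i, f"inpatient_mental_days_{w}"] * uc("inpatient_mental_day")
                    + df.loc[i, f"rehab_days_{w}"] * uc("rehab_day")
                )
                assert costs.loc[i, f"cost_inpatient_rehab_{w}"] == pytest.approx(expected, abs=1e-9)
                med = sum(
                    df.loc[i, f"packs_{code}_{w}"] * unit_table.pack_price_2019(code)
                    for code in unit_table.medication
                )
                assert costs.loc[i, f"cost_medication_{w}"] == pytest.approx(med, abs=1e-9)
                pres = (
                    (1 - df.loc[i, f"performance_{w}"] / 10)
                    * df.loc[i, f"days_at_work_{w}"]
                    * unit_table.daily_wage
                )
                assert costs.loc[i, f"cost_presenteeism_{w}"] == pytest.approx(pres, abs=1e-9)

    def test_unknown_medication_code_reported_not_dropped(self, unit_table):
        df = _zero_quantity_frame(3)
        df["packs_mystery_w1"] = [1.0, 0.0, 2.0]
        costs, rejects = cu.value_utilization(df, unit_table)
        assert list(rejects["code"]) == ["mystery"]
        assert rejects.loc[0, "n_nonzero"] == 2
        assert (costs["cost_medication_w1"] == 0).all()

    def test_missing_quantity_propagates(self, unit_table):
        df = _zero_quantity_frame(2)
        df.loc[0, "inpatient_days_w2"] = np.nan
        costs, _ = cu.value_utilization(df, unit_table)
        assert np.isnan(costs.loc[0, "cost_inpatient_rehab_w2"])
        assert costs.loc[1, "cost_inpatient_rehab_w2"] == 0


class TestWageValuation:
    def test_informal_care(self):
        assert cu.informal_care_cost(0, 20.0) == 0.0
        assert cu.informal_care_cost(10, 20.0) == pytest.approx(200.0)
        with pytest.raises(ValueError):
            cu.informal_care_cost(-1, 20.0)

    def test_informal_matches_formal_when_wages_equal(self, unit_table):
        hours = 7.5
        formal_rate = unit_table.unit_cost_2019("formal_care_hour")
        assert cu.informal_care_cost(hours, formal_rate) == pytest.approx(hours * formal_rate)

    def test_absenteeism(self):
        assert cu.absenteeism_cost(0, 200.0) == 0.0
        assert cu.absenteeism_cost(5, 200.0) == pytest.approx(1000.0)
        assert cu.absenteeism_cost(2.5, 200.0) == pytest.approx(500.0)
        with pytest.raises(ValueError):
            cu.absenteeism_cost(-0.5, 200.0)

    @pytest.mark.parametrize(
        "perf, days, wage, expected",
        [(10, 50, 300.0, 0.0), (0, 20, 200.0, 4000.0), (7, 100, 200.0, 6000.0)],
    )
    def test_presenteeism_values(self, perf, days, wage, expected):
        assert cu.presenteeism_cost(perf, days, wage) == pytest.approx(expected)

    def test_presenteeism_monotone_and_validated(self, rng):
        perf = np.sort(rng.uniform(0, 10, 50))
        costs = cu.presenteeism_cost(perf, 100, 200.0)
        assert (np.diff(costs) <= 1e-12).all()  # decreasing in performance
        with pytest.raises(ValueError):
            cu.presenteeism_cost(11, 10, 200.0)


class TestTotalsAndPerspectives:
    def test_intervention_loading(self):
        totals = pd.DataFrame({"total_societal_12m": [100.0, 100.0], "total_payer_12m": [50.0, 50.0]})
        arm = pd.Series(["CSC", "TAU"])
        out = cu.costing.load_intervention_costs(totals, arm, 139.0)
        assert out["cost_intervention"].tolist() == [139.0, 0.0]
        assert out["total_societal_12m"].tolist() == [239.0, 100.0]
        unchanged = cu.costing.load_intervention_costs(totals, arm, 0.0)
        assert unchanged["total_societal_12m"].tolist() == [100.0, 100.0]

    def test_perspective_totals_oracle(self):
        bd = pd.DataFrame(
            {
                "cost_outpatient_somatic": [5000.0],
                "cost_absenteeism": [8000.0],
                "cost_presenteeism": [13000.0],
            }
        )
        societal, payer = cu.perspective_totals(bd)
        assert societal.iloc[0] == pytest.approx(26000.0)
        assert payer.iloc[0] == pytest.approx(5000.0)

    def test_payer_never_exceeds_societal(self, rng):
        bd = pd.DataFrame(
            {f"cost_{c}": rng.gamma(1, 100, 50) for c in WINDOW_CATEGORIES}
        )
        societal, payer = cu.perspective_totals(bd)
        assert (payer <= societal + 1e-9).all()

    def test_untagged_category_rejected(self):
        with pytest.raises(ValueError, match="untagged"):
            cu.perspective_totals(pd.DataFrame({"cost_helicopter": [1.0]}))

    def test_category_additivity(self, valued_complete):
        """Societal total equals the sum of the eleven categories exactly."""
        bd = twelve_month_breakdown(valued_complete, valued_complete["arm"])
        parts = sum(bd[f"cost_{c}_12m"] for c in WINDOW_CATEGORIES) + bd["cost_intervention"]
        assert np.allclose(bd["total_societal_12m"], parts, atol=1e-9)
        indirect = bd["cost_absenteeism_12m"] + bd["cost_presenteeism_12m"]
        assert np.allclose(bd["total_payer_12m"], bd["total_societal_12m"] - indirect, atol=1e-9)

    def test_currency_invariance(self, complete_trial, unit_table):
        """Scaling every unit cost and wage by k scales every cost by k."""
        k = 1.75
        scaled = UnitCostTable(
            unit_costs={n: (c * k, y) for n, (c, y) in unit_table.unit_costs.items()},
            medication={
                code: {**e, "price": e["price"] * k} for code, e in unit_table.medication.items()
            },
            cpi=unit_table.cpi,
            informal_care_hourly_wage=unit_table.informal_care_hourly_wage * k,
            productivity_hourly_wage=unit_table.productivity_hourly_wage * k,
            contracted_hours_per_day=unit_table.contracted_hours_per_day,
        )
        base, _ = cu.value_utilization(complete_trial.complete, unit_table)
        big, _ = cu.value_utilization(complete_trial.complete, scaled)
        assert np.allclose(big.to_numpy(), k * base.to_numpy(), rtol=1e-12, equal_nan=True)

    def test_mental_health_subset_bounded_by_societal(self, valued_complete):
        bd = twelve_month_breakdown(valued_complete, valued_complete["arm"])
        subset = cu.mental_health_subset(bd)
        assert (subset <= bd["total_societal_12m"] + 1e-9).all()

    def test_mental_health_subset_zero_for_somatic_only(self, unit_table):
        df = _zero_quantity_frame(2)
        df["outpatient_somatic_contacts_w1"] = 5.0
        costs, _ = cu.value_utilization(df, unit_table)
        assert (costs["cost_mental_health_w1"] == 0).all()
        df["outpatient_mental_contacts_w2"] = 7.0
        costs, _ = cu.value_utilization(df, unit_table)
        assert costs.loc[0, "cost_mental_health_w2"] == pytest.approx(
            7.0 * unit_table.unit_cost_2019("outpatient_mental_contact")
        )


class TestWinsorize:
    def test_constant_vector_unchanged(self):
        x = np.full(20, 7.0)
        assert (cu.winsorize_p95(x) == x).all()

    def test_nearest_rank_on_1_to_100(self):
        x = np.arange(1.0, 101.0)
        out = cu.winsorize_p95(x)
        assert out.max() == 95.0
        assert (out[:95] == x[:95]).all()

    def test_mean_never_increases(self, rng):
        for _ in range(5):
            x = rng.gamma(0.6, 1000, 200)
            assert cu.winsorize_p95(x).mean() <= x.mean() + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cu.winsorize_p95([])
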