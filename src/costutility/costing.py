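"""Valuation of resource use and productivity losses in 2019 euros.

Utilization quantities from six-month recall windows (w0 at baseline, w1 at
6 months, w2 at 12 months) are multiplied by standardized unit costs,
inflated to 2019 price levels with a consumer price index.  Informal care is
valued by the replacement-cost method (market wage of a professional
substitute); absenteeism and presenteeism by the human capital approach
(gross wages).  Presenteeism for a window is::

    (1 - performance/10) * days_at_work * daily_wage

The societal perspective sums all eleven categories; the payer perspective
excludes the two indirect-cost categories (absenteeism, presenteeism).
Mean intervention costs are added to intervention-arm 12-month totals.

Shipped unit costs, wages and CPI values are documented placeholders in the
right order of magnitude for German care in 2019, not the official
catalogue; all of them load from YAML for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

TARGET_PRICE_YEAR = 2019

#: Cost categories of a six-month window breakdown, in reporting order.
WINDOW_CATEGORIES = [
    "inpatient_rehab",
    "outpatient_somatic",
    "outpatient_mental_health",
    "outpatient_nonphysician",
    "medical_aids",
    "medication",
    "nursing_formal",
    "nursing_informal",
    "absenteeism",
    "presenteeism",
]
#: intervention is loaded once per patient at the 12-month level.
CATEGORIES = WINDOW_CATEGORIES + ["intervention"]
INDIRECT_CATEGORIES = ["absenteeism", "presenteeism"]

#: mental / somatic / mixed tagging used for the mental-health-only analysis.
#: "mixed" categories carry an explicit mental-health memo computed at
#: valuation time (mental-health inpatient days; psychotropic packs).
CATEGORY_TAGS = {
    "inpatient_rehab": "mixed",
    "outpatient_somatic": "somatic",
    "outpatient_mental_health": "mental",
    "outpatient_nonphysician": "somatic",
    "medical_aids": "somatic",
    "medication": "mixed",
    "nursing_formal": "somatic",
    "nursing_informal": "somatic",
    "absenteeism": "indirect",
    "presenteeism": "indirect",
    "intervention": "mental",
}

WINDOWS = ("w0", "w1", "w2")


class ConfigurationError(ValueError):
    """Missing or invalid unit-cost configuration."""


@dataclass
class UnitCostTable:
    """Unit costs (€ per natural unit, each with a price year), wages and CPI."""

    unit_costs: dict = field(repr=False)  # name -> (euro, price_year)
    medication: dict = field(repr=False)  # code -> {"price": €, "price_year": y, "psychotropic": bool}
    cpi: dict = field(repr=False)  # year -> index value
    informal_care_hourly_wage: float = 24.0
    productivity_hourly_wage: float = 23.5
    contracted_hours_per_day: float = 8.0

    def __post_init__(self) -> None:
        for name, (cost, year) in self.unit_costs.items():
            if cost < 0:
                raise ConfigurationError(f"unit cost for {name!r} is negative")
            if year not in self.cpi:
                raise ConfigurationError(f"CPI entry missing for price year {year} ({name!r})")
        for code, entry in self.medication.items():
            if entry["price"] < 0:
                raise ConfigurationError(f"pack price for {code!r} is negative")
        if any(v <= 0 for v in self.cpi.values()):
            raise ConfigurationError("CPI values must be strictly positive")
        if TARGET_PRICE_YEAR not in self.cpi:
            raise ConfigurationError(f"CPI entry missing for target year {TARGET_PRICE_YEAR}")

    @property
    def daily_wage(self) -> float:
        """Cost of one day completely absent from work (human capital approach)."""
        return self.productivity_hourly_wage * self.contracted_hours_per_day

    def inflate_to_2019(self, amount: float, from_year: int) -> float:
        """amount × CPI(2019)/CPI(from_year)."""
        if from_year not in self.cpi:
            raise ConfigurationError(f"CPI entry missing for year {from_year}")
        return amount * self.cpi[TARGET_PRICE_YEAR] / self.cpi[from_year]

    def unit_cost_2019(self, name: str) -> float:
        if name not in self.unit_costs:
            raise ConfigurationError(f"no unit cost configured for {name!r}")
        cost, year = self.unit_costs[name]
        return self.inflate_to_2019(cost, year)

    def pack_price_2019(self, code: str) -> float:
        entry = self.medication[code]
        return self.inflate_to_2019(entry["price"], entry.get("price_year", TARGET_PRICE_YEAR))

    @classmethod
    def default(cls) -> "UnitCostTable":
        """Placeholder German 2019 table (documented approximations, editable via YAML)."""
        german_cpi = {2015: 97.9, 2016: 98.4, 2017: 99.9, 2018: 101.8, 2019: 103.1, 2020: 103.6}
        return cls(
            unit_costs={
                "inpatient_day": (575.0, 2019),
                "inpatient_mental_day": (450.0, 2019),
                "rehab_day": (140.0, 2015),
                "outpatient_somatic_contact": (35.0, 2019),
                "outpatient_mental_contact": (100.0, 2019),
                "nonphysician_contact": (25.0, 2019),
                "medical_aid_unit": (30.0, 2019),
                "formal_care_hour": (35.0, 2019),
            },
            medication={
                "antidepressant": {"price": 45.0, "price_year": 2019, "psychotropic": True},
                "anxiolytic": {"price": 35.0, "price_year": 2019, "psychotropic": True},
                "analgesic": {"price": 15.0, "price_year": 2019, "psychotropic": False},
                "antibiotic": {"price": 16.0, "price_year": 2019, "psychotropic": False},
            },
            cpi=german_cpi,
        )

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            unit_costs = {k: (float(v["cost"]), int(v["price_year"])) for k, v in raw["unit_costs"].items()}
            medication = {
                k: {
                    "price": float(v["price"]),
                    "price_year": int(v.get("price_year", TARGET_PRICE_YEAR)),
                    "psychotropic": bool(v.get("psychotropic", False)),
                }
                for k, v in raw["medication"].items()
            }
            cpi = {int(k): float(v) for k, v in raw["cpi"].items()}
            wages = raw.get("wages", {})
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed unit-cost YAML {path}: {exc}") from exc
        return cls(
            unit_costs=unit_costs,
            medication=medication,
            cpi=cpi,
            informal_care_hourly_wage=float(wages.get("informal_care_hourly", 24.0)),
            productivity_hourly_wage=float(wages.get("productivity_hourly", 23.5)),
            contracted_hours_per_day=float(wages.get("contracted_hours_per_day", 8.0)),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "unit_costs": {k: {"cost": c, "price_year": y} for k, (c, y) in self.unit_costs.items()},
            "medication": self.medication,
            "cpi": self.cpi,
            "wages": {
                "informal_care_hourly": self.informal_care_hourly_wage,
                "productivity_hourly": self.productivity_hourly_wage,
                "contracted_hours_per_day": self.contracted_hours_per_day,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def inflate_to_2019(amount: float, from_year: int, table: UnitCostTable) -> float:
    return table.inflate_to_2019(amount, from_year)


def informal_care_cost(hours, wage_substitute: float):
    """Replacement-cost valuation: hours of informal care × substitute wage."""
    h = np.asarray(hours, dtype=float)
    with np.errstate(invalid="ignore"):
        if (h < 0).any():
            raise ValueError("informal care hours must be nonnegative")
    out = h * wage_substitute
    return float(out) if out.ndim == 0 else out


def absenteeism_cost(days_absent, daily_wage: float):
    """Human capital valuation of full absence days (fractional days allowed)."""
    d = np.asarray(days_absent, dtype=float)
    with np.errstate(invalid="ignore"):
        if (d < 0).any():
            raise ValueError("days absent must be nonnegative")
    out = d * daily_wage
    return float(out) if out.ndim == 0 else out


def presenteeism_cost(performance_0_10, days_at_work, daily_wage: float):
    """(1 - performance/10) × days at work × cost of one fully absent day."""
    p = np.asarray(performance_0_10, dtype=float)
    d = np.asarray(days_at_work, dtype=float)
    with np.errstate(invalid="ignore"):
        if ((p < 0) | (p > 10)).any():
            raise ValueError("work performance must lie in [0, 10]")
        if (d < 0).any():
            raise ValueError("days at work must be nonnegative")
    out = (1.0 - p / 10.0) * d * daily_wage
    return float(out) if out.ndim == 0 else out


def _pack_columns(df: pd.DataFrame, window: str) -> list[str]:
    prefix, suffix = "packs_", f"_{window}"
    return [c for c in df.columns if c.startswith(prefix) and c.endswith(suffix)]


def value_utilization(records: pd.DataFrame, table: UnitCostTable):
    """Value per-window utilization quantities into per-window category costs.

    Returns ``(costs, rejects)``: *costs* has one column
    ``cost_<category>_<window>`` per category and window plus a
    ``cost_mental_health_<window>`` memo (mental-health inpatient days,
    outpatient mental health services, psychotropic medication), indexed like
    the input.  Missing quantities propagate to missing costs — they are
    never silently zeroed, so imputation can act on the cost scale.
    Unknown medication pack columns are listed in the *rejects* frame and
    excluded from the valuation rather than dropped silently.
    """
    costs = pd.DataFrame(index=records.index)
    rejects = []
    known_codes = set(table.medication)
    uc = table.unit_cost_2019
    daily_wage = table.daily_wage

    for w in WINDOWS:
        if f"inpatient_days_{w}" not in records.columns:
            continue
        inp = records[f"inpatient_days_{w}"] * uc("inpatient_day")
        inp_mental = records[f"inpatient_mental_days_{w}"] * uc("inpatient_mental_day")
        rehab = records[f"rehab_days_{w}"] * uc("rehab_day")
        costs[f"cost_inpatient_rehab_{w}"] = inp + inp_mental + rehab
        costs[f"cost_outpatient_somatic_{w}"] = records[f"outpatient_somatic_contacts_{w}"] * uc(
            "outpatient_somatic_contact"
        )
        costs[f"cost_outpatient_mental_health_{w}"] = records[f"outpatient_mental_contacts_{w}"] * uc(
            "outpatient_mental_contact"
        )
        costs[f"cost_outpatient_nonphysician_{w}"] = records[f"nonphysician_contacts_{w}"] * uc(
            "nonphysician_contact"
        )
        costs[f"cost_medical_aids_{w}"] = records[f"medical_aid_units_{w}"] * uc("medical_aid_unit")

        med_total = pd.Series(0.0, index=records.index)
        med_psy = pd.Series(0.0, index=records.index)
        for col in _pack_columns(records, w):
            code = col[len("packs_") : -len(f"_{w}")]
            if code not in known_codes:
                rejects.append({"column": col, "code": code, "n_nonzero": int((records[col].fillna(0) > 0).sum())})
                continue
            contribution = records[col] * table.pack_price_2019(code)
            med_total = med_total + contribution
            if table.medication[code]["psychotropic"]:
                med_psy = med_psy + contribution
        costs[f"cost_medication_{w}"] = med_total

        costs[f"cost_nursing_formal_{w}"] = records[f"formal_care_hours_{w}"] * uc("formal_care_hour")
        costs[f"cost_nursing_informal_{w}"] = informal_care_cost(
            records[f"informal_care_hours_{w}"].to_numpy(), table.informal_care_hourly_wage
        )
        costs[f"cost_absenteeism_{w}"] = records[f"days_absent_{w}"] * daily_wage
        costs[f"cost_presenteeism_{w}"] = (
            (1.0 - records[f"performance_{w}"] / 10.0) * records[f"days_at_work_{w}"] * daily_wage
        )
        costs[f"cost_mental_health_{w}"] = (
            inp_mental + costs[f"cost_outpatient_mental_health_{w}"] + med_psy
        )
    rejects_df = pd.DataFrame(rejects, columns=["column", "code", "n_nonzero"])
    return costs, rejects_df


def load_intervention_costs(totals: pd.DataFrame, arm: pd.Series, mean_intervention_cost: float = 139.0) -> pd.DataFrame:
    """Add the mean per-patient intervention cost to intervention-arm totals.

    Adds a ``cost_intervention`` column (0 for TAU) and increments societal
    and payer 12-month totals where present.
    """
    if mean_intervention_cost < 0:
        raise ValueError("mean intervention cost must be nonnegative")
    out = totals.copy()
    is_csc = (arm == "CSC").to_numpy()
    out["cost_intervention"] = np.where(is_csc, mean_intervention_cost, 0.0)
    for col in ("total_societal_12m", "total_payer_12m", "cost_mental_health_12m"):
        if col in out.columns:
            out[col] = out[col] + out["cost_intervention"]
    return out


def perspective_totals(breakdown: pd.DataFrame):
    """(societal, payer) totals from category columns (no window suffix).

    societal = sum of all categories; payer = societal − absenteeism −
    presenteeism.
    """
    cols = [c for c in breakdown.columns if c.startswith("cost_")]
    for c in cols:
        cat = c[len("cost_") :]
        if cat not in CATEGORY_TAGS and cat != "mental_health":
            raise ValueError(f"untagged cost category {cat!r}")
    cat_cols = [c for c in cols if c != "cost_mental_health"]
    societal = breakdown[cat_cols].sum(axis=1)
    indirect = sum(
        (breakdown[f"cost_{c}"] for c in INDIRECT_CATEGORIES if f"cost_{c}" in breakdown.columns),
        start=pd.Series(0.0, index=breakdown.index),
    )
    return societal, societal - indirect


def twelve_month_breakdown(
    costs: pd.DataFrame,
    arm: pd.Series,
    mean_intervention_cost: float = 139.0,
) -> pd.DataFrame:
    """Aggregate window costs into the 12-month analysis breakdown.

    Follow-up costs are the w1 + w2 windows (tiling the year); the w0 window
    is kept as the baseline-adjustment covariate.  Intervention costs are
    loaded onto intervention-arm totals.  NaN propagates (sums with any
    missing window stay missing until imputation).
    """
    out = pd.DataFrame(index=costs.index)
    for cat in WINDOW_CATEGORIES:
        out[f"cost_{cat}_12m"] = costs[f"cost_{cat}_w1"] + costs[f"cost_{cat}_w2"]
    out["cost_mental_health_12m"] = costs["cost_mental_health_w1"] + costs["cost_mental_health_w2"]
    base_cols = [f"cost_{cat}_w0" for cat in WINDOW_CATEGORIES]
    out["baseline_societal_w0"] = costs[base_cols].sum(axis=1, skipna=False)
    out["baseline_payer_w0"] = out["baseline_societal_w0"] - costs[
        [f"cost_{c}_w0" for c in INDIRECT_CATEGORIES]
    ].sum(axis=1, skipna=False)
    out["baseline_mental_health_w0"] = costs["cost_mental_health_w0"]

    follow_cols = [f"cost_{cat}_12m" for cat in WINDOW_CATEGORIES]
    out["total_societal_12m"] = out[follow_cols].sum(axis=1, skipna=False)
    out["total_payer_12m"] = out["total_societal_12m"] - out[
        [f"cost_{c}_12m" for c in INDIRECT_CATEGORIES]
    ].sum(axis=1, skipna=False)
    return load_intervention_costs(out, arm, mean_intervention_cost)


def winsorize_p95(values) -> np.ndarray:
    """Winsorize at the empirical 95th percentile (nearest-rank definition)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("winsorize_p95 requires a nonempty collection")
    finite = x[~np.isnan(x)]
    if finite.size == 0:
        raise ValueError("winsorize_p95 requires at least one observed value")
    rank = int(np.ceil(0.95 * finite.size)) - 1
    cutoff = np.sort(finite)[rank]
    return np.where(x > cutoff, cutoff, x)


def mental_health_subset(breakdown: pd.DataFrame) -> pd.Series:
    """12-month mental-health-related costs (inpatient mental care, outpatient
    mental health services, psychopharmacological medication, intervention)."""
    if "cost_mental_health_12m" not in breakdown.columns:
        raise ValueError("breakdown lacks the mental-health memo; run value_utilization first")
    return breakdown["cost_mental_health_12m"]
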