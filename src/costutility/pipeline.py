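"""End-to-end orchestration: utilities -> costs -> imputation -> models -> CEA.

One :class:`AnalysisConfig` selects a point on every analysis axis
(perspective, effect measure, missing-data strategy, subgroup, winsorization,
mental-health-only costs); :func:`run_analysis` executes the stages in order
under the intention-to-treat principle (every randomized patient retained)
and produces the descriptive baseline table, unadjusted and adjusted
cost/effect tables, the ICUR, the CEAC and the bootstrap cost-effectiveness
plane, plus a reproducibility manifest.  :func:`variant_matrix` enumerates
the additional-analysis families over the same pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cea import CeacCurve, CePlane, WtpGrid, ce_plane, ceac, icur
from .costing import (
    UnitCostTable,
    WINDOW_CATEGORIES,
    twelve_month_breakdown,
    value_utilization,
    winsorize_p95,
)
from .hrqol import AUDIT_CUTOFF, DIAGNOSIS_INSTRUMENT, REMISSION_CUTOFFS, qaly_trapezoid
from .impute import complete_cases, locf, mice_pmm
from .models import (
    Adjustment,
    DEFAULT_COVARIATES,
    baseline_tests,
    fit_cost_model,
    fit_effect_model,
    pool_fit_results,
)
from .synthetic import summarize_baseline

PERSPECTIVES = ("societal", "payer")
EFFECT_MEASURES = ("qaly_eq5d", "qaly_vas", "qaly_sf6d", "response", "remission")
MISSING_STRATEGIES = ("mice", "locf", "complete_case")
SUBGROUPS = ("all", "depressive", "anxiety", "somatoform", "alcohol")

MICE_PREDICTOR_COVARIATES = [
    "arm",
    "sex",
    "age",
    "occupational_status",
    "main_diagnosis",
    "n_comorbidities",
    "covid_pre",
    "recruit_planned",
    "mcs_t0",
]


class SubgroupInfeasibleError(RuntimeError):
    """A subgroup left one arm empty, so the comparison cannot be estimated."""


@dataclass
class AnalysisConfig:
    perspective: str = "societal"
    effect_measure: str = "qaly_eq5d"
    missing_strategy: str = "mice"
    subgroup: str = "all"
    winsorize: bool = False
    mental_health_only: bool = False
    wtp_lower: float = 0.0
    wtp_upper: float = 50_000.0
    wtp_step: float = 1_000.0
    m: int = 20
    donors: int = 5
    iterations: int = 10
    se_method: str = "jackknife"  # SE of adjusted differences: jackknife | bootstrap
    n_boot: int = 200  # bootstrap draws per adjusted-difference SE (se_method='bootstrap')
    n_boot_plane: int = 1000
    mean_intervention_cost: float = 139.0
    zero_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        checks = (
            ("perspective", self.perspective, PERSPECTIVES),
            ("effect_measure", self.effect_measure, EFFECT_MEASURES),
            ("missing_strategy", self.missing_strategy, MISSING_STRATEGIES),
            ("subgroup", self.subgroup, SUBGROUPS),
        )
        for name, value, allowed in checks:
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")

    def wtp_grid(self) -> WtpGrid:
        return WtpGrid(self.wtp_lower, self.wtp_upper, self.wtp_step)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ReportBundle:
    config: AnalysisConfig
    baseline_table: pd.DataFrame = field(repr=False)
    baseline_pvalues: pd.DataFrame = field(repr=False)
    unadjusted_table: pd.DataFrame = field(repr=False)
    adjusted_table: pd.DataFrame = field(repr=False)
    icur_result: object = None
    ceac_curve: CeacCurve | None = None
    plane: CePlane | None = None
    n_patients: dict = field(default_factory=dict)
    missing_report: dict = field(default_factory=dict)
    rejects: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "baseline_table.csv": self.baseline_table,
            "baseline_pvalues.csv": self.baseline_pvalues,
            "unadjusted_table.csv": self.unadjusted_table,
            "adjusted_table.csv": self.adjusted_table,
        }
        for name, df in files.items():
            df.to_csv(out / name, index=False)
        if self.ceac_curve is not None:
            self.ceac_curve.to_csv(out / "ceac.csv")
            self.ceac_curve.plot(out / "ceac.png")
        if self.plane is not None:
            self.plane.to_csv(out / "ce_plane.csv")
            with open(out / "ce_plane_quadrants.json", "w") as fh:
                json.dump(self.plane.quadrant_shares, fh, indent=2)
            self.plane.plot(out / "ce_plane.png")
        manifest = dict(self.manifest)
        manifest["outputs"] = {}
        for f in sorted(out.iterdir()):
            if f.name == "manifest.json" or f.suffix == ".png":
                continue
            manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        self.manifest = manifest
        return manifest


# ---------------------------------------------------------------------------
# derived analysis columns


def _cost_window_columns() -> list:
    return [f"cost_{cat}_{w}" for cat in WINDOW_CATEGORIES for w in ("w0", "w1", "w2")] + [
        f"cost_mental_health_{w}" for w in ("w0", "w1", "w2")
    ]


def _matching_symptom(df: pd.DataFrame, visit: str) -> pd.Series:
    instr = df["main_diagnosis"].map(DIAGNOSIS_INSTRUMENT)
    out = pd.Series(np.nan, index=df.index)
    for name in set(DIAGNOSIS_INSTRUMENT.values()):
        sel = instr == name
        out.loc[sel] = df.loc[sel, f"{name}_{visit}"]
    return out


def derive_outcomes(frame: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Attach 12-month cost totals, QALYs and response/remission columns."""
    df = frame.copy()
    bd = twelve_month_breakdown(df, df["arm"], config.mean_intervention_cost)
    df = pd.concat([df, bd], axis=1)
    for w in ("w0", "w1", "w2"):
        cats = [f"cost_{cat}_{w}" for cat in WINDOW_CATEGORIES]
        df[f"total_societal_{w}"] = df[cats].sum(axis=1, skipna=False)
        df[f"total_payer_{w}"] = df[f"total_societal_{w}"] - df[
            [f"cost_absenteeism_{w}", f"cost_presenteeism_{w}"]
        ].sum(axis=1, skipna=False)
    df["qaly_eq5d"] = 0.25 * df["eq5d_t0"] + 0.5 * df["eq5d_t1"] + 0.25 * df["eq5d_t2"]
    df["qaly_vas"] = (0.25 * df["eqvas_t0"] + 0.5 * df["eqvas_t1"] + 0.25 * df["eqvas_t2"]) / 100.0
    df["qaly_sf6d"] = 0.25 * df["sf6d_t0"] + 0.5 * df["sf6d_t1"] + 0.25 * df["sf6d_t2"]

    base = _matching_symptom(df, "t0")
    follow = _matching_symptom(df, "t2")
    df["symptom_base"] = base
    with np.errstate(divide="ignore", invalid="ignore"):
        improvement = (base - follow) / base
    # response undefined at baseline 0: no room for 50% improvement
    df["response"] = np.where(base > 0, improvement >= 0.5, False).astype(float)
    instr = df["main_diagnosis"].map(DIAGNOSIS_INSTRUMENT)
    cutoff = instr.map(REMISSION_CUTOFFS).astype(float)
    audit_cut = df["sex"].map(AUDIT_CUTOFF).astype(float)
    cutoff = cutoff.where(instr != "audit", audit_cut)
    df["remission"] = (follow < cutoff).astype(float)
    return df


def _analysis_cost_column(config: AnalysisConfig) -> tuple:
    """(12-month cost column, its baseline-window column) for the chosen axis."""
    if config.mental_health_only:
        return "cost_mental_health_12m", "baseline_mental_health_w0"
    if config.perspective == "payer":
        return "total_payer_12m", "baseline_payer_w0"
    return "total_societal_12m", "baseline_societal_w0"


_EFFECT_BASELINE = {
    "qaly_eq5d": "eq5d_t0",
    "qaly_vas": "eqvas_t0",
    "qaly_sf6d": "sf6d_t0",
    "response": "symptom_base",
    "remission": "symptom_base",
}


# ---------------------------------------------------------------------------


def _apply_missing_strategy(analysis: pd.DataFrame, config: AnalysisConfig):
    """Returns (list of completed frames, missing report)."""
    outcome_cols = [
        c
        for c in analysis.columns
        if any(c.startswith(f"{m}_t") for m in ("eq5d", "eqvas", "sf6d", "phq9", "gad7", "phq15", "audit"))
    ]
    cost_cols = [c for c in _cost_window_columns() if c in analysis.columns]
    impute_vars = outcome_cols + cost_cols
    report = {
        "strategy": config.missing_strategy,
        "n_rows": len(analysis),
        "incomplete_rows": int(analysis[impute_vars].isna().any(axis=1).sum()),
    }
    if config.missing_strategy == "mice":
        if analysis[impute_vars].isna().any().any():
            imputed = mice_pmm(
                analysis,
                variables=impute_vars,
                predictors=[c for c in MICE_PREDICTOR_COVARIATES if c in analysis.columns],
                m=config.m,
                donors=config.donors,
                iterations=config.iterations,
                seed=config.seed,
            )
            return list(imputed), report
        return [analysis.copy() for _ in range(config.m)], report
    if config.missing_strategy == "locf":
        filled = locf(analysis)
        cc = complete_cases(filled, impute_vars)
        report["retained_after_locf"] = cc.n_retained
    else:
        cc = complete_cases(analysis, impute_vars)
        report["retained"] = cc.n_retained
    kept = cc.data.reset_index(drop=True)
    counts = kept["arm"].value_counts() if not kept.empty else {}
    if kept.empty or counts.get("CSC", 0) == 0 or counts.get("TAU", 0) == 0:
        raise ValueError(
            f"{config.missing_strategy} filtering left an arm empty "
            f"({cc.n_retained} of {len(analysis)} rows retained)"
        )
    return [kept], report


def _unadjusted_table(datasets: list) -> pd.DataFrame:
    """Unadjusted arm means (SE) per visit/window with Rubin-pooled differences."""
    variables = (
        [f"total_payer_{w}" for w in ("w0", "w1", "w2")]
        + [f"total_societal_{w}" for w in ("w0", "w1", "w2")]
        + [f"{m}_{t}" for m in ("eq5d", "eqvas", "sf6d") for t in ("t0", "t1", "t2")]
    )
    rows = []
    for var in variables:
        if var not in datasets[0].columns:
            continue
        mc, mt, vd = [], [], []
        for df in datasets:
            g = df.groupby("arm")[var]
            means, sems = g.mean(), g.sem()
            mc.append(means.get("CSC", np.nan))
            mt.append(means.get("TAU", np.nan))
            vd.append(sems.get("CSC", np.nan) ** 2 + sems.get("TAU", np.nan) ** 2)
        mc, mt, vd = map(np.asarray, (mc, mt, vd))
        diff = mc - mt
        m = len(datasets)
        if m > 1:
            total_var = vd.mean() + (1 + 1 / m) * diff.var(ddof=1)
        else:
            total_var = vd[0]
        se = float(np.sqrt(total_var))
        from scipy import stats as _st

        p = 2 * _st.norm.sf(abs(diff.mean()) / se) if se > 0 else 1.0
        rows.append(
            {
                "variable": var,
                "mean_csc": float(mc.mean()),
                "mean_tau": float(mt.mean()),
                "difference": float(diff.mean()),
                "se": se,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def _adjusted_table(datasets: list, config: AnalysisConfig) -> pd.DataFrame:
    """Table-3-style adjusted differences pooled across imputations."""
    outcomes = []
    for cat in WINDOW_CATEGORIES:
        outcomes.append((f"cost_{cat}_12m", "cost", f"cost_{cat}_w0"))
    outcomes.append(("cost_mental_health_12m", "cost", "baseline_mental_health_w0"))
    outcomes.append(("total_payer_12m", "cost", "baseline_payer_w0"))
    outcomes.append(("total_societal_12m", "cost", "baseline_societal_w0"))
    for eff in ("qaly_eq5d", "qaly_vas", "qaly_sf6d"):
        outcomes.append((eff, "effect", _EFFECT_BASELINE[eff]))
    if config.effect_measure in ("response", "remission"):
        outcomes.append((config.effect_measure, "effect", "symptom_base"))

    rows = []
    dfcom = len(datasets[0]) - 12
    for outcome, kind, baseline in outcomes:
        fits = []
        try:
            for i, df in enumerate(datasets):
                adj = Adjustment.standard(baseline if baseline in df.columns else None)
                if kind == "cost":
                    fits.append(
                        fit_cost_model(
                            df, outcome, adj, zero_threshold=config.zero_threshold,
                            se_method=config.se_method,
                            n_boot=config.n_boot, seed=config.seed + 17 * i,
                        )
                    )
                else:
                    fits.append(
                        fit_effect_model(
                            df, outcome, adj, se_method=config.se_method,
                            n_boot=config.n_boot, seed=config.seed + 17 * i,
                        )
                    )
            pooled = pool_fit_results(fits, dfcom=dfcom) if len(fits) > 1 else fits[0].summary_row()
        except Exception as exc:  # per-outcome failures reported, not fatal
            rows.append({"outcome": outcome, "error": str(exc)})
            continue
        pooled.pop("pooled", None)
        rows.append({"outcome": outcome, **pooled})
    return pd.DataFrame(rows)


def run_analysis(
    observed: pd.DataFrame,
    config: AnalysisConfig | None = None,
    unit_costs: UnitCostTable | None = None,
) -> ReportBundle:
    """Execute the full cost-utility analysis on one (masked) trial dataset."""
    config = config or AnalysisConfig()
    config.validate()
    table = unit_costs or UnitCostTable.default()

    data = observed.copy()
    if config.subgroup != "all":
        data = data[data["main_diagnosis"] == config.subgroup].reset_index(drop=True)
        counts = data["arm"].value_counts()
        if counts.get("CSC", 0) == 0 or counts.get("TAU", 0) == 0:
            raise SubgroupInfeasibleError(
                f"subgroup {config.subgroup!r} analysis not possible: "
                f"no patients in the {'CSC' if counts.get('CSC', 0) == 0 else 'TAU'} group"
            )

    baseline_table = summarize_baseline(data)
    baseline_cols = ["sex", "age", "occupational_status", "main_diagnosis",
                     "n_comorbidities", "covid_pre", "recruit_planned", "mcs_t0"]
    baseline_pvalues = baseline_tests(data, [c for c in baseline_cols if c in data.columns])

    costs, rejects = value_utilization(data, table)
    analysis = pd.concat([data, costs], axis=1)

    completed, missing_report = _apply_missing_strategy(analysis, config)
    derived = [derive_outcomes(df, config) for df in completed]

    cost_col, baseline_cost_col = _analysis_cost_column(config)
    if config.winsorize:
        for df in derived:
            df[cost_col] = winsorize_p95(df[cost_col].to_numpy())
    effect_col = config.effect_measure

    unadj = _unadjusted_table(derived)
    adj_table = _adjusted_table(derived, config)

    # ICUR from unadjusted pooled means of the analysis cost/effect pair
    d_cost = float(np.mean([_arm_diff(df, cost_col) for df in derived]))
    d_eff = float(np.mean([_arm_diff(df, effect_col) for df in derived]))
    icur_result = icur(d_cost, d_eff)

    nb_adjustment = Adjustment(
        covariates=tuple(DEFAULT_COVARIATES)
        + (baseline_cost_col, _EFFECT_BASELINE[effect_col]),
        baseline=None,
    )
    curve = ceac(derived, effect_col, cost_col, nb_adjustment, config.wtp_grid())
    plane = ce_plane(
        derived, effect_col, cost_col, nb_adjustment,
        n_boot=config.n_boot_plane, seed=config.seed,
    )

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": _versions(),
        "n_patients": {arm: int((data["arm"] == arm).sum()) for arm in ("CSC", "TAU")},
        "missing": missing_report,
    }
    return ReportBundle(
        config=config,
        baseline_table=baseline_table,
        baseline_pvalues=baseline_pvalues,
        unadjusted_table=unadj,
        adjusted_table=adj_table,
        icur_result=icur_result,
        ceac_curve=curve,
        plane=plane,
        n_patients=manifest["n_patients"],
        missing_report=missing_report,
        rejects=rejects,
        manifest=manifest,
    )


def _arm_diff(df: pd.DataFrame, col: str) -> float:
    g = df.groupby("arm")[col].mean()
    return float(g.get("CSC", np.nan) - g.get("TAU", np.nan))


def _versions() -> dict:
    import statsmodels

    return {
        "costutility": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def variant_matrix(
    observed: pd.DataFrame,
    base_config: AnalysisConfig | None = None,
    unit_costs: UnitCostTable | None = None,
    out_dir=None,
) -> dict:
    """Run the main analysis and the six additional-analysis families.

    Per-variant failures (e.g. an infeasible subgroup) are captured as error
    strings without aborting the matrix.
    """
    base = base_config or AnalysisConfig()
    variants = {"main": {}}
    variants.update(
        {
            "payer": {"perspective": "payer"},
            "qaly_vas": {"effect_measure": "qaly_vas"},
            "qaly_sf6d": {"effect_measure": "qaly_sf6d"},
            "response": {"effect_measure": "response"},
            "remission": {"effect_measure": "remission"},
            "subgroup_depressive": {"subgroup": "depressive"},
            "subgroup_anxiety": {"subgroup": "anxiety"},
            "subgroup_somatoform": {"subgroup": "somatoform"},
            "subgroup_alcohol": {"subgroup": "alcohol"},
            "winsorized": {"winsorize": True},
            "mental_health_costs": {"mental_health_only": True},
            "locf": {"missing_strategy": "locf"},
            "complete_case": {"missing_strategy": "complete_case"},
        }
    )
    results: dict[str, object] = {}
    for name, overrides in variants.items():
        cfg = dataclasses.replace(base, **overrides)
        try:
            bundle = run_analysis(observed, cfg, unit_costs)
            if out_dir is not None:
                bundle.write(pathlib.Path(out_dir) / name)
            results[name] = bundle
        except (SubgroupInfeasibleError, Exception) as exc:
            results[name] = f"error: {exc}"
    return results


def format_euro(amount: float) -> str:
    """Display formatter reproducing the '1,234€' style used in reports."""
    return f"{amount:,.0f}€"
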