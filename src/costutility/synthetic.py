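"""Seeded synthetic cluster-randomized two-arm trial generator.

Emulates the data structure of a primary-care trial comparing a collaborative
and stepped care model (CSC) against treatment as usual (TAU) for the four
most common mental disorders: practice-level randomization, baseline
covariate imbalance, right-skewed six-month resource-use quantities from
hurdle (Bernoulli x gamma) processes with a shared patient severity factor
and practice random effects, utility trajectories at T0/T1/T2, symptom
scores, work data, and covariate-dependent (MAR) missingness applied after
outcome generation.  The complete-data copy is retained next to the masked
copy so downstream stages can be tested against the generator's own truth.

Defaults mirror the arm sizes (307/308), baseline marginals and mean outcome
trajectories reported for the emulated trial; cluster counts and the
intraclass correlation are assumptions (20 practices/arm, ICC 0.02), not
reported facts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

ARMS = ("CSC", "TAU")
VISITS = ("t0", "t1", "t2")
WINDOWS = ("w0", "w1", "w2")

OCCUPATION_LEVELS = ("full_time", "part_time", "marginal", "not_employed")
DIAGNOSIS_LEVELS = ("depressive", "anxiety", "somatoform", "alcohol")

#: outcome measures carried at each visit
OUTCOME_MEASURES = ("eq5d", "eqvas", "sf6d", "phq9", "gad7", "phq15", "audit")
#: utilization quantities carried for each recall window
QUANTITY_NAMES = (
    "inpatient_days",
    "inpatient_mental_days",
    "rehab_days",
    "outpatient_somatic_contacts",
    "outpatient_mental_contacts",
    "nonphysician_contacts",
    "medical_aid_units",
    "packs_antidepressant",
    "packs_anxiolytic",
    "packs_analgesic",
    "packs_antibiotic",
    "formal_care_hours",
    "informal_care_hours",
    "days_absent",
    "days_at_work",
    "performance",
)
_COUNT_QUANTITIES = {
    "outpatient_somatic_contacts",
    "outpatient_mental_contacts",
    "nonphysician_contacts",
    "medical_aid_units",
    "packs_antidepressant",
    "packs_anxiolytic",
    "packs_analgesic",
    "packs_antibiotic",
}

COVARIATE_COLUMNS = (
    "sex",
    "age",
    "occupational_status",
    "main_diagnosis",
    "n_comorbidities",
    "covid_pre",
    "recruit_planned",
    "mcs_t0",
)


class TrialConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise TrialConfigError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass
class HurdleQuantity:
    """Hurdle model for one utilization quantity per six-month window.

    ``p_any`` and ``mean_if_positive`` are per-arm; the positive part is
    gamma with the given shape whose mean is modulated multiplicatively by
    the patient severity factor and the practice effect on the log scale
    (mean-corrected, so the unconditional category mean stays exactly
    ``p_any * mean_if_positive``).
    """

    p_any: dict
    mean_if_positive: dict
    shape: float = 1.0
    sigma_log: float = 0.5
    z_share: float = 0.7  # share of sigma_log^2 carried by the severity factor

    def validate(self, name: str) -> None:
        for arm in ARMS:
            _check_prob(f"{name}.p_any[{arm}]", self.p_any[arm])
            if self.mean_if_positive[arm] < 0:
                raise TrialConfigError(f"{name}.mean_if_positive[{arm}] must be >= 0")
        if self.shape <= 0:
            raise TrialConfigError(f"{name}.shape must be > 0")
        if self.sigma_log < 0:
            raise TrialConfigError(f"{name}.sigma_log must be >= 0")
        _check_prob(f"{name}.z_share", self.z_share)

    def log_multiplier_variance(self) -> float:
        return self.sigma_log**2


@dataclass
class UtilityMeasure:
    """Censored-normal generator for one utility/score measure at T0/T1/T2."""

    means: dict  # arm -> (t0, t1, t2) target means of the *censored* variable
    sd: float
    lo: float
    hi: float
    z_share: float = 0.35
    integer: bool = False

    def validate(self, name: str) -> None:
        if self.sd <= 0:
            raise TrialConfigError(f"{name}.sd must be > 0")
        if self.lo >= self.hi:
            raise TrialConfigError(f"{name}: lo must be < hi")
        _check_prob(f"{name}.z_share", self.z_share)


@dataclass
class MissingnessConfig:
    """Per-visit MAR rates; probability is logistic in arm and baseline MCS.

    ``outcome_rates`` / ``utilization_rates`` are the *marginal* per-variable
    missingness rates at T0/T1/T2.  Missingness is blocky, as in real
    longitudinal trials: a ``dropout_share`` of each rate is carried by a
    visit-level dropout event that masks every outcome and utilization
    variable of that visit, the rest by independent item nonresponse — so
    complete cases remain a realistic minority rather than vanishing.
    """

    outcome_rates: tuple = (0.04, 0.22, 0.33)
    utilization_rates: tuple = (0.05, 0.24, 0.34)
    dropout_share: float = 0.95
    b_arm_tau: float = 0.4
    b_mcs: float = -0.35  # per 10 MCS points above 35

    def validate(self) -> None:
        for nm, rates in (("outcome_rates", self.outcome_rates), ("utilization_rates", self.utilization_rates)):
            if len(rates) != 3:
                raise TrialConfigError(f"missingness.{nm} must have 3 entries")
            for r in rates:
                _check_prob(f"missingness.{nm}", r)
        _check_prob("missingness.dropout_share", self.dropout_share)

    @classmethod
    def none(cls) -> "MissingnessConfig":
        return cls(outcome_rates=(0.0, 0.0, 0.0), utilization_rates=(0.0, 0.0, 0.0))


def _default_quantities() -> dict:
    q = {
        "inpatient_days": HurdleQuantity({"CSC": 0.08, "TAU": 0.08}, {"CSC": 14.0, "TAU": 14.0}, 0.9),
        "inpatient_mental_days": HurdleQuantity({"CSC": 0.05, "TAU": 0.04}, {"CSC": 20.0, "TAU": 18.0}, 0.9),
        "rehab_days": HurdleQuantity({"CSC": 0.03, "TAU": 0.03}, {"CSC": 21.0, "TAU": 21.0}, 1.2),
        "outpatient_somatic_contacts": HurdleQuantity({"CSC": 0.95, "TAU": 0.95}, {"CSC": 11.0, "TAU": 11.0}, 1.1),
        "outpatient_mental_contacts": HurdleQuantity({"CSC": 0.70, "TAU": 0.48}, {"CSC": 10.5, "TAU": 7.5}, 1.0),
        "nonphysician_contacts": HurdleQuantity({"CSC": 0.50, "TAU": 0.50}, {"CSC": 9.0, "TAU": 9.0}, 1.0),
        "medical_aid_units": HurdleQuantity({"CSC": 0.12, "TAU": 0.12}, {"CSC": 1.6, "TAU": 1.6}, 1.0),
        "packs_antidepressant": HurdleQuantity({"CSC": 0.60, "TAU": 0.55}, {"CSC": 3.6, "TAU": 3.6}, 1.0),
        "packs_anxiolytic": HurdleQuantity({"CSC": 0.18, "TAU": 0.18}, {"CSC": 2.2, "TAU": 2.2}, 1.0),
        "packs_analgesic": HurdleQuantity({"CSC": 0.55, "TAU": 0.55}, {"CSC": 2.5, "TAU": 2.5}, 1.0),
        "packs_antibiotic": HurdleQuantity({"CSC": 0.25, "TAU": 0.25}, {"CSC": 1.6, "TAU": 1.6}, 1.0),
        "formal_care_hours": HurdleQuantity({"CSC": 0.05, "TAU": 0.05}, {"CSC": 35.0, "TAU": 35.0}, 0.8),
        "informal_care_hours": HurdleQuantity({"CSC": 0.06, "TAU": 0.06}, {"CSC": 10.0, "TAU": 10.0}, 0.8),
        "days_absent": HurdleQuantity({"CSC": 0.60, "TAU": 0.55}, {"CSC": 34.0, "TAU": 32.0}, 0.7),
    }
    return q


def _default_utilities() -> dict:
    return {
        "eq5d": UtilityMeasure(
            {"CSC": (0.81, 0.89, 0.90), "TAU": (0.83, 0.88, 0.89)}, sd=0.175, lo=-0.661, hi=1.0
        ),
        "eqvas": UtilityMeasure(
            {"CSC": (63.91, 68.63, 71.12), "TAU": (67.68, 70.73, 69.82)}, sd=21.0, lo=0.0, hi=100.0
        ),
        "sf6d": UtilityMeasure(
            {"CSC": (0.59, 0.70, 0.71), "TAU": (0.64, 0.72, 0.71)}, sd=0.12, lo=0.0, hi=1.0
        ),
        "phq9": UtilityMeasure(
            {"CSC": (12.0, 8.5, 7.5), "TAU": (12.0, 8.5, 7.5)}, sd=5.5, lo=0, hi=27, z_share=0.5, integer=True
        ),
        "gad7": UtilityMeasure(
            {"CSC": (9.0, 6.5, 6.0), "TAU": (9.0, 6.5, 6.0)}, sd=4.5, lo=0, hi=21, z_share=0.5, integer=True
        ),
        "phq15": UtilityMeasure(
            {"CSC": (11.0, 9.0, 8.5), "TAU": (11.0, 9.0, 8.5)}, sd=5.0, lo=0, hi=30, z_share=0.5, integer=True
        ),
        "audit": UtilityMeasure(
            {"CSC": (4.0, 3.5, 3.2), "TAU": (4.0, 3.5, 3.2)}, sd=5.0, lo=0, hi=40, z_share=0.5, integer=True
        ),
    }


def _default_covariates() -> dict:
    # Baseline marginals per arm mirroring the emulated trial's Table-1 roles.
    return {
        "p_female": {"CSC": 0.6124, "TAU": 0.6656},
        "age_mean": {"CSC": 37.71, "TAU": 43.26},
        "age_sd": {"CSC": 12.4, "TAU": 14.9},
        "occupational_status": {
            "CSC": (0.5606, 0.1967, 0.0492, 0.1935),
            "TAU": (0.5131, 0.2123, 0.0169, 0.2577),
        },
        "main_diagnosis": {
            "CSC": (0.7362, 0.2052, 0.0586, 0.0),
            "TAU": (0.7825, 0.0974, 0.0941, 0.0260),
        },
        "n_comorbidities": {
            "CSC": (0.7068, 0.2410, 0.0392, 0.0130),
            "TAU": (0.6851, 0.2013, 0.0844, 0.0292),
        },
        "p_covid_pre": {"CSC": 0.9055, "TAU": 0.6786},
        "p_recruit_planned": {"CSC": 0.9577, "TAU": 0.5909},
        "mcs_mean": {"CSC": 35.0, "TAU": 35.0},
        "mcs_sd": 10.0,
    }


@dataclass
class TrialConfig:
    """Full configuration of the synthetic cluster-randomized trial."""

    n_patients: dict = field(default_factory=lambda: {"CSC": 307, "TAU": 308})
    n_practices_per_arm: int = 20
    practice_size_dispersion: float = 10.0  # Dirichlet concentration per practice
    icc: float = 0.02  # practice share of utility variance (assumption)
    covariates: dict = field(default_factory=_default_covariates)
    utilities: dict = field(default_factory=_default_utilities)
    quantities: dict = field(default_factory=_default_quantities)
    #: CSC multiplier on baseline-window (w0) mean resource use - the
    #: baseline cost-imbalance knob (intervention arm costlier at T0).
    baseline_cost_multiplier_csc: float = 1.18
    #: additive shifts for the CSC arm at T1/T2 on each utility measure
    arm_utility_effects: dict = field(default_factory=dict)
    #: additive € shifts on the unconditional CSC mean of a cost quantity,
    #: expressed in natural units of that quantity (applied on the latent
    #: scale so the injected difference is exact in expectation)
    arm_quantity_effects: dict = field(default_factory=dict)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    mean_intervention_cost: float = 139.0
    workdays_mean: float = 127.0
    workdays_sd: float = 10.0
    performance_mean: float = 7.2
    performance_sd: float = 1.8
    seed: int = 0

    def validate(self) -> None:
        for arm in ARMS:
            if self.n_patients[arm] < 1:
                raise TrialConfigError(f"n_patients[{arm}] must be >= 1")
        if self.n_practices_per_arm < 1:
            raise TrialConfigError("n_practices_per_arm must be >= 1")
        if self.practice_size_dispersion <= 0:
            raise TrialConfigError("practice_size_dispersion must be > 0")
        _check_prob("icc", self.icc)
        cov = self.covariates
        for nm in ("p_female", "p_covid_pre", "p_recruit_planned"):
            for arm in ARMS:
                _check_prob(f"covariates.{nm}[{arm}]", cov[nm][arm])
        for nm in ("occupational_status", "main_diagnosis", "n_comorbidities"):
            for arm in ARMS:
                probs = cov[nm][arm]
                for p in probs:
                    _check_prob(f"covariates.{nm}[{arm}]", p)
                if abs(sum(probs) - 1.0) > 1e-6:
                    raise TrialConfigError(f"covariates.{nm}[{arm}] must sum to 1")
        for name, um in self.utilities.items():
            um.validate(f"utilities.{name}")
        for name, hq in self.quantities.items():
            hq.validate(f"quantities.{name}")
        self.missingness.validate()
        if self.mean_intervention_cost < 0:
            raise TrialConfigError("mean_intervention_cost must be >= 0")

    @classmethod
    def default(cls, seed: int = 0) -> "TrialConfig":
        return cls(seed=seed)

    @classmethod
    def null(cls, seed: int = 0, n_per_arm: int | None = None, missingness: bool = False) -> "TrialConfig":
        """Balanced arms, no arm effects: both arms share averaged marginals.

        The null configuration backs law-of-large-numbers and coverage tests.
        """
        cfg = cls(seed=seed)
        cov = cfg.covariates
        for nm in ("p_female", "p_covid_pre", "p_recruit_planned", "age_mean", "mcs_mean"):
            avg = (cov[nm]["CSC"] + cov[nm]["TAU"]) / 2.0
            cov[nm] = {"CSC": avg, "TAU": avg}
        cov["age_sd"] = {"CSC": 13.6, "TAU": 13.6}
        for nm in ("occupational_status", "main_diagnosis", "n_comorbidities"):
            avg = tuple((a + b) / 2.0 for a, b in zip(cov[nm]["CSC"], cov[nm]["TAU"]))
            cov[nm] = {"CSC": avg, "TAU": avg}
        for um in cfg.utilities.values():
            avg = tuple((a + b) / 2.0 for a, b in zip(um.means["CSC"], um.means["TAU"]))
            um.means = {"CSC": avg, "TAU": avg}
        for hq in cfg.quantities.values():
            p = (hq.p_any["CSC"] + hq.p_any["TAU"]) / 2.0
            mu = (hq.mean_if_positive["CSC"] + hq.mean_if_positive["TAU"]) / 2.0
            hq.p_any = {"CSC": p, "TAU": p}
            hq.mean_if_positive = {"CSC": mu, "TAU": mu}
        cfg.baseline_cost_multiplier_csc = 1.0
        if not missingness:
            cfg.missingness = MissingnessConfig.none()
        if n_per_arm is not None:
            cfg.n_patients = {"CSC": n_per_arm, "TAU": n_per_arm}
        return cfg

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, raw: dict) -> "TrialConfig":
        raw = dict(raw)
        raw["utilities"] = {
            k: UtilityMeasure(**{**v, "means": {a: tuple(m) for a, m in v["means"].items()}})
            for k, v in raw.get("utilities", {}).items()
        }
        raw["quantities"] = {k: HurdleQuantity(**v) for k, v in raw.get("quantities", {}).items()}
        if "missingness" in raw and isinstance(raw["missingness"], dict):
            ms = dict(raw["missingness"])
            for key in ("outcome_rates", "utilization_rates"):
                if key in ms:
                    ms[key] = tuple(ms[key])
            raw["missingness"] = MissingnessConfig(**ms)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SyntheticTrial:
    """Masked (``observed``) and complete copies of one generated trial."""

    observed: pd.DataFrame
    complete: pd.DataFrame
    config: TrialConfig

    def write(self, directory) -> None:
        """Tidy CSV (one row per patient-visit-window) plus a JSON sidecar."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        to_tidy(self.observed).to_csv(directory / "trial_observed.csv", index=False)
        to_tidy(self.complete).to_csv(directory / "trial_complete.csv", index=False)
        with open(directory / "trial_config.json", "w") as fh:
            json.dump({"seed": self.config.seed, "config": self.config.to_dict()}, fh, indent=2)


# ---------------------------------------------------------------------------


def _censored_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    return (
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        + sd * (norm.pdf(a) - norm.pdf(b))
    )


def _latent_mean_for_target(target: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal mean whose [lo, hi]-censored mean equals ``target``."""
    if not lo < target < hi:
        raise TrialConfigError(f"target mean {target} outside the open interval ({lo}, {hi})")
    span = hi - lo
    return brentq(
        lambda m: _censored_normal_mean(m, sd, lo, hi) - target,
        lo - 10 * sd - span,
        hi + 10 * sd + span,
        xtol=1e-10,
    )


def _calibrated_intercept(rate: float, offsets: np.ndarray) -> float:
    """Intercept c with mean(expit(c + offsets)) == rate (exact calibration)."""
    if rate <= 0.0:
        return -np.inf
    if rate >= 1.0:
        return np.inf
    return brentq(lambda c: expit(c + offsets).mean() - rate, -40.0, 40.0, xtol=1e-12)


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unbiased rounding to integers: floor(x) + Bernoulli(frac(x))."""
    fl = np.floor(x)
    return fl + (rng.random(x.shape) < (x - fl))


def generate_trial(config: TrialConfig) -> SyntheticTrial:
    """Generate one seeded trial; reproducible bit-for-bit given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov = config.covariates

    frames = []
    practice_counter = 0
    for arm in ARMS:
        n = config.n_patients[arm]
        k = min(config.n_practices_per_arm, n)
        weights = rng.dirichlet(np.full(k, config.practice_size_dispersion))
        sizes = rng.multinomial(n, weights)
        # every practice recruits at least one patient
        while (sizes == 0).any():
            empty = np.flatnonzero(sizes == 0)[0]
            sizes[empty] += 1
            sizes[np.argmax(sizes)] -= 1
        practice_ids = np.repeat(
            [f"P{practice_counter + j:03d}" for j in range(k)], sizes
        )
        practice_counter += k
        practice_effect = np.repeat(rng.standard_normal(k), sizes)

        df = pd.DataFrame(
            {
                "practice_id": practice_ids,
                "arm": arm,
                "_practice_eff": practice_effect,
            }
        )
        df["sex"] = np.where(rng.random(n) < cov["p_female"][arm], "female", "male")
        df["age"] = np.clip(rng.normal(cov["age_mean"][arm], cov["age_sd"][arm], n), 18.0, 90.0)
        df["occupational_status"] = rng.choice(
            OCCUPATION_LEVELS, size=n, p=np.asarray(cov["occupational_status"][arm])
        )
        df["main_diagnosis"] = rng.choice(
            DIAGNOSIS_LEVELS, size=n, p=np.asarray(cov["main_diagnosis"][arm])
        )
        df["n_comorbidities"] = rng.choice(4, size=n, p=np.asarray(cov["n_comorbidities"][arm]))
        df["covid_pre"] = (rng.random(n) < cov["p_covid_pre"][arm]).astype(int)
        df["recruit_planned"] = (rng.random(n) < cov["p_recruit_planned"][arm]).astype(int)

        z = rng.standard_normal(n)  # patient severity factor
        df["_z"] = z
        df["mcs_t0"] = cov["mcs_mean"][arm] + cov["mcs_sd"] * (
            -0.5 * z + np.sqrt(0.75) * rng.standard_normal(n)
        )

        _generate_outcomes(df, config, arm, rng)
        _generate_quantities(df, config, arm, rng)
        frames.append(df)

    complete = pd.concat(frames, ignore_index=True)
    complete.insert(0, "patient_id", [f"S{i:04d}" for i in range(len(complete))])
    complete = complete.drop(columns=["_z", "_practice_eff"])

    observed = _apply_missingness(complete, config, rng)
    return SyntheticTrial(observed=observed, complete=complete, config=config)


def _generate_outcomes(df: pd.DataFrame, config: TrialConfig, arm: str, rng: np.random.Generator) -> None:
    n = len(df)
    z = df["_z"].to_numpy()
    prac = df["_practice_eff"].to_numpy()
    diag = df["main_diagnosis"].to_numpy()
    from .hrqol import DIAGNOSIS_INSTRUMENT

    instrument_of = {v: k for k, v in DIAGNOSIS_INSTRUMENT.items()}  # phq9 -> depressive
    for name, um in config.utilities.items():
        sign = 1.0 if name in ("phq9", "gad7", "phq15", "audit") else -1.0  # symptoms rise with severity
        w_z = np.sqrt(um.z_share)
        w_p = np.sqrt(config.icc)
        w_e = np.sqrt(max(1.0 - um.z_share - config.icc, 0.0))
        for t_idx, visit in enumerate(VISITS):
            target = um.means[arm][t_idx]
            if visit != "t0":
                target = target + config.arm_utility_effects.get(name, 0.0) * (arm == "CSC")
            bump = 0.0
            if name in instrument_of:
                bump = np.where(diag == instrument_of[name], 3.0 if visit == "t0" else 2.0, 0.0)
                latent_mu = np.asarray(
                    [_latent_mean_for_target(min(t, um.hi - 1e-9), um.sd, um.lo, um.hi) for t in np.atleast_1d(target + np.unique(bump))]
                )
                # map each patient to the latent mean for its bump value
                mu_map = dict(zip(np.unique(bump), latent_mu))
                mu = np.vectorize(mu_map.get)(bump)
            else:
                mu = _latent_mean_for_target(target, um.sd, um.lo, um.hi)
            latent = mu + um.sd * (sign * w_z * z + w_p * prac + w_e * rng.standard_normal(n))
            vals = np.clip(latent, um.lo, um.hi)
            if um.integer:
                vals = np.clip(np.round(vals), um.lo, um.hi)
            df[f"{name}_{visit}"] = vals


def _generate_quantities(df: pd.DataFrame, config: TrialConfig, arm: str, rng: np.random.Generator) -> None:
    n = len(df)
    z = df["_z"].to_numpy()
    prac = df["_practice_eff"].to_numpy()
    employed = (df["occupational_status"] != "not_employed").to_numpy()

    for w_idx, window in enumerate(WINDOWS):
        base_mult = (
            config.baseline_cost_multiplier_csc if (window == "w0" and arm == "CSC") else 1.0
        )
        for name, hq in config.quantities.items():
            p = hq.p_any[arm]
            mu_pos = hq.mean_if_positive[arm] * base_mult
            if window != "w0" and arm == "CSC" and name in config.arm_quantity_effects:
                if p <= 0:
                    raise TrialConfigError(
                        f"arm_quantity_effects[{name!r}] requires p_any > 0 in the CSC arm"
                    )
                mu_pos = mu_pos + config.arm_quantity_effects[name] / p
            g_z = hq.sigma_log * np.sqrt(hq.z_share)
            g_p = hq.sigma_log * np.sqrt(1.0 - hq.z_share)
            log_mult = g_z * z + g_p * prac - 0.5 * (g_z**2 + g_p**2)
            mu_i = mu_pos * np.exp(log_mult)
            any_use = rng.random(n) < p
            positive = rng.gamma(hq.shape, mu_i / hq.shape)
            vals = np.where(any_use, positive, 0.0)
            if name == "days_absent":
                vals = np.where(employed, vals, 0.0)
                workdays = np.clip(rng.normal(config.workdays_mean, config.workdays_sd, n), 60.0, 140.0)
                df[f"days_at_work_{window}"] = np.where(employed, np.maximum(workdays - vals, 0.0), 0.0)
                perf = np.clip(
                    rng.normal(config.performance_mean, config.performance_sd, n) - 0.5 * z,
                    0.0,
                    10.0,
                )
                # not employed: no presenteeism loss by construction
                df[f"performance_{window}"] = np.where(employed, perf, 10.0)
                df[f"days_absent_{window}"] = vals
            else:
                if name in _COUNT_QUANTITIES:
                    vals = _stochastic_round(vals, rng)
                df[f"{name}_{window}"] = vals


def maskable_columns(df: pd.DataFrame) -> dict:
    """Columns subject to MAR masking, grouped as (kind, visit_index)."""
    groups: dict[tuple, list] = {}
    for name in OUTCOME_MEASURES:
        for t_idx, visit in enumerate(VISITS):
            col = f"{name}_{visit}"
            if col in df.columns:
                groups.setdefault(("outcome", t_idx), []).append(col)
    for name in QUANTITY_NAMES:
        for w_idx, window in enumerate(WINDOWS):
            col = f"{name}_{window}"
            if col in df.columns:
                groups.setdefault(("utilization", w_idx), []).append(col)
    return groups


def _apply_missingness(complete: pd.DataFrame, config: TrialConfig, rng: np.random.Generator) -> pd.DataFrame:
    ms = config.missingness
    observed = complete.copy()
    n = len(complete)
    offsets = (
        ms.b_arm_tau * (complete["arm"] == "TAU").to_numpy(float)
        + ms.b_mcs * (complete["mcs_t0"].to_numpy() - 35.0) / 10.0
    )
    groups = maskable_columns(complete)
    for idx in range(3):
        rates = {
            "outcome": ms.outcome_rates[idx],
            "utilization": ms.utilization_rates[idx],
        }
        if all(r <= 0 for r in rates.values()):
            continue
        # visit-level dropout shared by all variables of the visit
        d = ms.dropout_share * min(r for r in rates.values() if r > 0)
        if d > 0:
            p_drop = expit(_calibrated_intercept(d, offsets) + offsets)
            dropped = rng.random(n) < p_drop
        else:
            p_drop = np.zeros(n)
            dropped = np.zeros(n, dtype=bool)
        for kind, rate in rates.items():
            cols = groups.get((kind, idx), [])
            if rate <= 0 or not cols:
                continue
            residual = rate - d
            p_item = None
            if residual > 1e-12:
                # calibrate item nonresponse so the marginal rate is exact
                # despite the overlap with (correlated) dropout probabilities
                c = brentq(
                    lambda c: np.mean((1.0 - p_drop) * expit(c + offsets)) - residual,
                    -40.0,
                    40.0,
                    xtol=1e-12,
                )
                p_item = expit(c + offsets)
            for col in cols:
                mask = dropped.copy()
                if p_item is not None:
                    mask |= rng.random(n) < p_item
                observed.loc[mask, col] = np.nan
    return observed


# ---------------------------------------------------------------------------


def to_tidy(wide: pd.DataFrame) -> pd.DataFrame:
    """One row per patient-visit-window (visit k pairs with recall window k)."""
    rows = []
    id_cols = ["patient_id", "practice_id", "arm", *COVARIATE_COLUMNS]
    id_cols = [c for c in dict.fromkeys(id_cols) if c in wide.columns]
    for k, (visit, window) in enumerate(zip(VISITS, WINDOWS)):
        chunk = wide[id_cols].copy()
        chunk["visit"] = visit
        for name in OUTCOME_MEASURES:
            col = f"{name}_{visit}"
            if col in wide.columns:
                chunk[name] = wide[col].to_numpy()
        for name in QUANTITY_NAMES:
            col = f"{name}_{window}"
            if col in wide.columns:
                chunk[name] = wide[col].to_numpy()
        rows.append(chunk)
    return pd.concat(rows, ignore_index=True).sort_values(["patient_id", "visit"], kind="stable").reset_index(drop=True)


def from_tidy(tidy: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_tidy`."""
    id_cols = [c for c in ("patient_id", "practice_id", "arm", *COVARIATE_COLUMNS) if c in tidy.columns]
    base = tidy.drop_duplicates("patient_id")[id_cols].set_index("patient_id")
    for k, (visit, window) in enumerate(zip(VISITS, WINDOWS)):
        sub = tidy[tidy["visit"] == visit].set_index("patient_id")
        for name in OUTCOME_MEASURES:
            if name in sub.columns:
                base[f"{name}_{visit}"] = sub[name]
        for name in QUANTITY_NAMES:
            if name in sub.columns:
                base[f"{name}_{window}"] = sub[name]
    return base.reset_index()


def summarize_baseline(records: pd.DataFrame) -> pd.DataFrame:
    """Per-arm descriptive baseline table: n (%) per categorical level,
    mean (SE) for continuous variables.  Zero-count levels appear as 0 (0.00%)."""
    if records.empty:
        raise ValueError("records must be nonempty")
    rows = []
    levels = {
        "sex": ("female", "male"),
        "occupational_status": OCCUPATION_LEVELS,
        "main_diagnosis": DIAGNOSIS_LEVELS,
        "n_comorbidities": (0, 1, 2, 3),
        "covid_pre": (1, 0),
        "recruit_planned": (1, 0),
    }
    by_arm = {arm: records[records["arm"] == arm] for arm in ARMS}
    for var in ("age", "mcs_t0"):
        if var not in records.columns:
            continue
        row = {"variable": var, "level": "mean (SE)"}
        for arm, sub in by_arm.items():
            x = sub[var].dropna()
            se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
            row[f"{arm}"] = f"{x.mean():.2f} ({se:.2f})"
            row[f"{arm}_value"] = x.mean()
        rows.append(row)
    for var, lvls in levels.items():
        if var not in records.columns:
            continue
        for lvl in lvls:
            row = {"variable": var, "level": str(lvl)}
            for arm, sub in by_arm.items():
                count = int((sub[var] == lvl).sum())
                pct = 100.0 * count / len(sub) if len(sub) else 0.0
                row[f"{arm}"] = f"{count} ({pct:.2f}%)"
                row[f"{arm}_value"] = pct / 100.0
            rows.append(row)
    return pd.DataFrame(rows)
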