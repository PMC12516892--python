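"""Health-state utilities, QALYs and symptom-based outcomes.

The EQ-5D-5L descriptive system has five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression) with five ordinal
levels each, so it can describe ``5**5 = 3125`` health states.  A value set
maps each profile to a societal utility; the German-anchored convention used
throughout this package runs from 1 (profile 11111, no problems in any
dimension) down to -0.661 (profile 55555, extreme problems in all five).

QALYs over the 12-month trial horizon are computed by the trapezoid rule on
the three assessments T0 (baseline), T1 (6 months) and T2 (12 months), each
half-year weighted 0.5::

    QALY = 0.5 * (u_T0 + u_T1) / 2 + 0.5 * (u_T1 + u_T2) / 2

Negative utilities (states valued worse than dead) are retained unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")
N_LEVELS = 5
N_PROFILES = N_LEVELS ** len(DIMENSIONS)  # 3125

# Placeholder additive-decrement tariff anchored at 1 (11111) and -0.661
# (55555).  Shaped loosely like published EQ-5D-5L value sets (pain and
# anxiety/depression carry the largest weights); NOT the licensed German
# coefficients, which can be supplied via ValueSet.from_csv.
_WORST_DECREMENT = {
    "mobility": 0.274,
    "self_care": 0.288,
    "usual_activities": 0.264,
    "pain_discomfort": 0.403,
    "anxiety_depression": 0.432,
}
_LEVEL_FRACTION = {1: 0.0, 2: 0.12, 3: 0.25, 4: 0.60, 5: 1.0}


class ProfileError(ValueError):
    """A dimension level outside 1..5."""


@dataclass(frozen=True)
class ValueSet:
    """Maps EQ-5D-5L profiles to utilities via an additive decrement table.

    ``decrements[(dimension, level)]`` is subtracted from 1; level 1 always
    contributes 0.  Utilities are clamped to ``[anchor_worst, 1]``.
    """

    name: str
    decrements: dict = field(repr=False)
    anchor_worst: float = -0.661

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            if abs(self.decrements.get((dim, 1), 0.0)) > 1e-12:
                raise ValueError(f"level-1 decrement for {dim!r} must be 0")
        worst = 1.0 - sum(self.decrements[(d, 5)] for d in DIMENSIONS)
        if abs(worst - self.anchor_worst) > 1e-9:
            raise ValueError(
                f"decrement table inconsistent with anchor_worst: "
                f"worst profile maps to {worst:.6f}, expected {self.anchor_worst}"
            )

    @classmethod
    def default_german_anchored(cls) -> "ValueSet":
        dec = {}
        for dim in DIMENSIONS:
            for lvl in range(1, 6):
                dec[(dim, lvl)] = _WORST_DECREMENT[dim] * _LEVEL_FRACTION[lvl]
        return cls(name="placeholder-german-anchored", decrements=dec)

    @classmethod
    def from_csv(cls, path, name: str | None = None, anchor_worst: float = -0.661) -> "ValueSet":
        """Load a decrement table from CSV with columns dimension, level, decrement."""
        df = pd.read_csv(path)
        required = {"dimension", "level", "decrement"}
        if set(df.columns) != required:
            raise ValueError(f"value-set CSV must have exactly columns {sorted(required)}, got {list(df.columns)}")
        unknown = set(df["dimension"]) - set(DIMENSIONS)
        if unknown:
            raise ValueError(f"unknown dimensions in value-set CSV: {sorted(unknown)}")
        dec = {(r.dimension, int(r.level)): float(r.decrement) for r in df.itertuples()}
        for dim in DIMENSIONS:
            dec.setdefault((dim, 1), 0.0)
            for lvl in range(2, 6):
                if (dim, lvl) not in dec:
                    raise ValueError(f"value-set CSV missing entry for ({dim}, {lvl})")
        return cls(name=name or str(path), decrements=dec, anchor_worst=anchor_worst)

    def index(self, profile) -> float:
        """Utility of one 5-tuple of levels (1..5 each)."""
        if len(profile) != len(DIMENSIONS):
            raise ProfileError(f"profile must have {len(DIMENSIONS)} levels, got {len(profile)}")
        total = 1.0
        for dim, lvl in zip(DIMENSIONS, profile):
            lvl = int(lvl)
            if not 1 <= lvl <= N_LEVELS:
                raise ProfileError(f"{dim} level {lvl} outside 1..5")
            total -= self.decrements[(dim, lvl)]
        return float(min(1.0, max(self.anchor_worst, total)))

    def enumerate_profiles(self) -> pd.DataFrame:
        """All 3,125 profiles with their utilities."""
        rows = [(p, self.index(p)) for p in itertools.product(range(1, 6), repeat=5)]
        return pd.DataFrame(
            {"profile": ["".join(map(str, p)) for p, _ in rows], "utility": [u for _, u in rows]}
        )


def index_from_profile(profile, value_set: ValueSet | None = None) -> float:
    """EQ-5D-5L index for one profile under a value set (default placeholder)."""
    vs = value_set or ValueSet.default_german_anchored()
    return vs.index(profile)


def qaly_trapezoid(u_t0, u_t1, u_t2):
    """Trapezoid QALY over two half-year intervals; accepts scalars or arrays.

    Missing (NaN) utilities raise: imputation must run first.
    """
    u0, u1, u2 = (np.asarray(u, dtype=float) for u in (u_t0, u_t1, u_t2))
    if np.isnan(u0).any() or np.isnan(u1).any() or np.isnan(u2).any():
        raise ValueError("missing utility in trajectory; impute before computing QALYs")
    q = 0.5 * (u0 + u1) / 2.0 + 0.5 * (u1 + u2) / 2.0
    return float(q) if q.ndim == 0 else q


def qaly_from_vas(v_t0, v_t1, v_t2):
    """QALY from EQ-VAS scores (0-100), each divided by 100 before weighting."""
    arrs = [np.asarray(v, dtype=float) for v in (v_t0, v_t1, v_t2)]
    for a in arrs:
        with np.errstate(invalid="ignore"):
            if ((a < 0) | (a > 100)).any():
                raise ValueError("EQ-VAS scores must lie in [0, 100]")
    return qaly_trapezoid(*(a / 100.0 for a in arrs))


def response(baseline_score, followup_score) -> bool:
    """Treatment response: symptom score improved by at least 50% from baseline."""
    b = float(baseline_score)
    f = float(followup_score)
    if not b > 0:
        raise ValueError("response undefined for baseline score <= 0")
    return (b - f) / b >= 0.5


# Remission cutoffs: strict inequalities.  AUDIT cutoff depends on sex.
REMISSION_CUTOFFS = {"phq9": 5, "gad7": 5, "phq15": 9}
AUDIT_CUTOFF = {"female": 4, "male": 5}

INSTRUMENT_RANGES = {"phq9": (0, 27), "gad7": (0, 21), "phq15": (0, 30), "audit": (0, 40)}
DIAGNOSIS_INSTRUMENT = {
    "depressive": "phq9",
    "anxiety": "gad7",
    "somatoform": "phq15",
    "alcohol": "audit",
}


@dataclass(frozen=True)
class SymptomPanel:
    """Follow-up symptom severity scores plus sex (needed for the AUDIT cutoff)."""

    phq9: float | None = None
    gad7: float | None = None
    phq15: float | None = None
    audit: float | None = None
    sex: str | None = None


def remission(panel: SymptomPanel) -> dict:
    """Instrument-wise remission booleans plus 'combined' (all present instruments).

    PHQ-9 < 5, GAD-7 < 5, PHQ-15 < 9; AUDIT < 4 for females and < 5 for males.
    """
    out: dict[str, bool] = {}
    for name, cut in REMISSION_CUTOFFS.items():
        score = getattr(panel, name)
        if score is not None and not (isinstance(score, float) and np.isnan(score)):
            _check_range(name, score)
            out[name] = float(score) < cut
    if panel.audit is not None and not (isinstance(panel.audit, float) and np.isnan(panel.audit)):
        if panel.sex not in AUDIT_CUTOFF:
            raise ValueError("sex ('female'/'male') required to evaluate AUDIT remission")
        _check_range("audit", panel.audit)
        out["audit"] = float(panel.audit) < AUDIT_CUTOFF[panel.sex]
    if not out:
        raise ValueError("no follow-up symptom scores present")
    out["combined"] = all(v for k, v in out.items())
    return out


def _check_range(name: str, score) -> None:
    lo, hi = INSTRUMENT_RANGES[name]
    if not lo <= float(score) <= hi:
        raise ValueError(f"{name} score {score} outside [{lo}, {hi}]")
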