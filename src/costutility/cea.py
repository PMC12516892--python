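"""Incremental cost-utility ratio, net-benefit regressions and CEAC.

The ICUR is the ratio of the (unadjusted) difference in mean 12-month total
costs to the difference in mean QALYs.  Its uncertainty is summarized by a
cost-effectiveness acceptability curve (CEAC): for each willingness-to-pay
threshold λ on a grid (default 0 to 50,000€ in 1,000€ steps) the individual
net monetary benefit::

    NB_i(λ) = λ * QALY_i − cost_i

is regressed on the arm indicator plus the adjustment covariates with robust
standard errors, the arm coefficient is pooled across imputations by Rubin's
rules, and the probability of cost-effectiveness is ``1 − p/2`` for a
positive pooled coefficient, ``p/2`` for a negative one and 0.5 at exactly
zero.  A cluster-bootstrap cost-effectiveness plane of adjusted incremental
cost and QALY pairs complements the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import Adjustment, build_design, pool_rubin


@dataclass(frozen=True)
class WtpGrid:
    """Willingness-to-pay grid in € per QALY (or per response/remission)."""

    lower: float = 0.0
    upper: float = 50_000.0
    step: float = 1_000.0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("WTP grid lower bound exceeds upper bound")
        if self.step <= 0:
            raise ValueError("WTP grid step must be positive")

    def values(self) -> np.ndarray:
        n = int(np.floor((self.upper - self.lower) / self.step + 1e-9)) + 1
        return self.lower + self.step * np.arange(n)


@dataclass(frozen=True)
class IcurResult:
    delta_cost: float
    delta_qaly: float
    ratio: float | None
    flag: str  # NE | SW | dominant | dominated | undefined


def icur(delta_cost: float, delta_qaly: float, tol: float = 1e-9) -> IcurResult:
    """Incremental cost-utility ratio with quadrant/dominance classification."""
    dc, dq = float(delta_cost), float(delta_qaly)
    if not (np.isfinite(dc) and np.isfinite(dq)):
        raise ValueError("ICUR requires finite cost and QALY differences")
    if abs(dq) < tol:
        return IcurResult(dc, dq, None, "undefined")
    if dc >= 0 and dq > 0:
        flag = "NE"
    elif dc < 0 and dq > 0:
        flag = "dominant"
    elif dc >= 0 and dq < 0:
        flag = "dominated"
    else:
        flag = "SW"
    return IcurResult(dc, dq, dc / dq, flag)


def net_benefit(wtp, qaly, cost):
    """Net monetary benefit λ·QALY − cost; λ must be nonnegative."""
    lam = np.asarray(wtp, dtype=float)
    if (lam < 0).any():
        raise ValueError("willingness-to-pay must be nonnegative")
    out = lam * np.asarray(qaly, dtype=float) - np.asarray(cost, dtype=float)
    return float(out) if out.ndim == 0 else out


def ceac_probability(coefficient: float, p_value: float) -> float:
    """Probability of cost-effectiveness from one pooled net-benefit regression."""
    if coefficient > 0:
        return 1.0 - p_value / 2.0
    if coefficient < 0:
        return p_value / 2.0
    return 0.5


@dataclass
class CeacCurve:
    """(WTP, probability) points with the pooled arm coefficients behind them."""

    points: pd.DataFrame = field(repr=False)  # wtp, probability, coefficient, p_value

    def probability_at(self, wtp: float) -> float:
        idx = (self.points["wtp"] - wtp).abs().idxmin()
        return float(self.points.loc[idx, "probability"])

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    def plot(self, path=None, label: str | None = None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.points["wtp"], self.points["probability"], marker="", lw=2, label=label)
        ax.set_xlabel("Willingness to pay per additional QALY (€)")
        ax.set_ylabel("Probability of cost-effectiveness")
        ax.set_ylim(0, 1)
        ax.grid(alpha=0.3)
        if label:
            ax.legend()
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
            return None
        return fig


def _arm_coef_robust(design, nb: np.ndarray):
    """Arm coefficient and HC1 variance for every WTP column of ``nb`` at once."""
    X = design.X
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ nb)  # (k, L)
    resid = nb - X @ beta  # (n, L)
    h = X @ XtX_inv[:, design.arm_index]  # (n,)
    var = (h**2) @ (resid**2) * (n / (n - k))  # (L,)
    return beta[design.arm_index], var


def ceac(
    imputed,
    qaly_col: str,
    cost_col: str,
    adjustment: Adjustment | None = None,
    grid: WtpGrid | None = None,
) -> CeacCurve:
    """CEAC from net-benefit regressions pooled across imputations.

    ``imputed`` is an ImputationSet or any iterable of completed DataFrames
    carrying ``qaly_col`` and ``cost_col``.
    """
    datasets = list(imputed)
    if not datasets:
        raise ValueError("no imputed datasets supplied")
    grid = grid or WtpGrid()
    lam = grid.values()
    if lam.size == 0:
        raise ValueError("empty WTP grid")

    coefs, variances = [], []
    dfcom = None
    for df in datasets:
        design = build_design(df, adjustment)
        q = df[qaly_col].to_numpy(float)
        c = df[cost_col].to_numpy(float)
        if np.isnan(q).any() or np.isnan(c).any():
            raise ValueError("QALYs and costs must be complete within each imputation")
        nb = q[:, None] * lam[None, :] - c[:, None]
        b, v = _arm_coef_robust(design, nb)
        coefs.append(b)
        variances.append(v)
        dfcom = len(df) - design.X.shape[1]
    coefs = np.asarray(coefs)  # (m, L)
    variances = np.asarray(variances)

    rows = []
    if len(datasets) == 1:
        se = np.sqrt(variances[0])
        t = np.divide(coefs[0], se, out=np.zeros_like(se), where=se > 0)
        pvals = 2.0 * stats.t.sf(np.abs(t), dfcom)
        for lam_l, b_l, p_l in zip(lam, coefs[0], pvals):
            rows.append(
                {"wtp": lam_l, "probability": ceac_probability(b_l, p_l), "coefficient": b_l, "p_value": p_l}
            )
    else:
        for j, lam_l in enumerate(lam):
            pooled = pool_rubin(coefs[:, j], variances[:, j], dfcom=dfcom)
            rows.append(
                {
                    "wtp": lam_l,
                    "probability": ceac_probability(pooled.estimate, pooled.p_value),
                    "coefficient": pooled.estimate,
                    "p_value": pooled.p_value,
                }
            )
    return CeacCurve(points=pd.DataFrame(rows))


@dataclass
class CePlane:
    """Cluster-bootstrap replicates of (incremental cost, incremental QALY)."""

    replicates: pd.DataFrame = field(repr=False)  # delta_cost, delta_qaly
    quadrant_shares: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index=False)

    def plot(self, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5.5, 5))
        ax.scatter(self.replicates["delta_qaly"], self.replicates["delta_cost"], s=6, alpha=0.4)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental costs (€)")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
            return None
        return fig


def ce_plane(
    imputed,
    qaly_col: str,
    cost_col: str,
    adjustment: Adjustment | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    loop_imputations: bool = False,
) -> CePlane:
    """Bootstrap the adjusted incremental cost/QALY pair by resampling practices.

    Works within the first imputed dataset by default; with
    ``loop_imputations`` replicates cycle over all imputations.
    """
    datasets = list(imputed)
    if n_boot < 100:
        raise ValueError("ce_plane needs at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    pool = datasets if loop_imputations else datasets[:1]
    prepared = []
    for df in pool:
        design = build_design(df, adjustment)
        y = np.column_stack([df[cost_col].to_numpy(float), df[qaly_col].to_numpy(float)])
        rows_of = {g: np.flatnonzero(design.groups == g) for g in np.unique(design.groups)}
        arm_groups = {
            arm: [g for g, a in design.group_arm.items() if a == arm] for arm in ("CSC", "TAU")
        }
        prepared.append((design, y, rows_of, arm_groups))

    reps = []
    for r in range(n_boot):
        design, y, rows_of, arm_groups = prepared[r % len(prepared)]
        idx_parts = []
        for arm, glist in arm_groups.items():
            if not glist:
                continue
            chosen = rng.choice(glist, size=len(glist), replace=True)
            idx_parts.extend(rows_of[g] for g in chosen)
        idx = np.concatenate(idx_parts)
        Xb = design.X[idx]
        beta, *_ = np.linalg.lstsq(Xb, y[idx], rcond=None)
        # linear recycled predictions: adjusted difference = arm coefficient
        reps.append((beta[design.arm_index, 0], beta[design.arm_index, 1]))
    rep_df = pd.DataFrame(reps, columns=["delta_cost", "delta_qaly"])
    north = rep_df["delta_cost"].to_numpy() > 0
    east = rep_df["delta_qaly"].to_numpy() > 0
    shares = {
        "NE": float((north & east).mean()),
        "NW": float((north & ~east).mean()),
        "SE": float((~north & east).mean()),
        "SW": float((~north & ~east).mean()),
    }
    return CePlane(replicates=rep_df, quadrant_shares=shares)
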