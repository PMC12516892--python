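"""Adjusted group differences for costs and health effects.

Costs are right-skewed with point mass at zero, so the cost endpoint uses a
two-part model (logit for any cost, gamma GLM with log link for positive
cost) when the zero fraction reaches a threshold (default 5%), and a single
gamma-log GLM otherwise.  Health effects use a gamma-log GLM when strictly
positive and a linear model with robust standard errors otherwise (EQ-5D
QALYs can be negative).  Adjusted per-arm means come from recycled
predictions (marginal standardization): every patient is predicted under
both arm assignments and the predictions averaged.  The standard error of
the adjusted difference is obtained by a nonparametric bootstrap that
resamples practices within arm, respecting the cluster randomization.
Estimates from multiply imputed datasets are pooled by Rubin's rules with
Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))

DEFAULT_COVARIATES = (
    "sex",
    "age",
    "occupational_status",
    "main_diagnosis",
    "covid_pre",
    "n_comorbidities",
    "mcs_t0",
)


class DegenerateModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Adjustment:
    """Covariate set plus the baseline measurement of the modeled outcome."""

    covariates: tuple = DEFAULT_COVARIATES
    baseline: str | None = None

    @classmethod
    def none(cls) -> "Adjustment":
        return cls(covariates=(), baseline=None)

    @classmethod
    def standard(cls, baseline: str | None) -> "Adjustment":
        return cls(covariates=DEFAULT_COVARIATES, baseline=baseline)


@dataclass
class Design:
    X: np.ndarray
    names: list
    arm_index: int
    X_csc: np.ndarray
    X_tau: np.ndarray
    groups: np.ndarray  # integer practice codes
    group_arm: dict  # practice code -> arm label
    dropped: list


def build_design(df: pd.DataFrame, adjustment: Adjustment | None) -> Design:
    """Intercept + arm indicator + encoded covariates (+ baseline value)."""
    adjustment = adjustment or Adjustment.none()
    n = len(df)
    cols = [np.ones(n)]
    names = ["const"]
    arm = (df["arm"] == "CSC").to_numpy(float)
    cols.append(arm)
    names.append("arm_csc")
    arm_index = 1
    terms = list(adjustment.covariates)
    if adjustment.baseline:
        terms.append(adjustment.baseline)
    for col in terms:
        s = df[col]
        if s.isna().any():
            raise ValueError(f"adjustment variable {col!r} contains missing values; impute first")
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.astype(str)))
            for lvl in levels[1:]:
                cols.append((s.astype(str) == lvl).to_numpy(float))
                names.append(f"{col}[{lvl}]")
        else:
            cols.append(s.to_numpy(float))
            names.append(col)
    X = np.column_stack(cols)
    # drop constant non-intercept columns so the design is full rank
    keep, dropped = [0], []
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0 and j != arm_index:
            dropped.append(names[j])
        else:
            keep.append(j)
    X = X[:, keep]
    names = [names[j] for j in keep]
    arm_index = names.index("arm_csc")
    X_csc = X.copy()
    X_csc[:, arm_index] = 1.0
    X_tau = X.copy()
    X_tau[:, arm_index] = 0.0
    codes, uniques = pd.factorize(df["practice_id"], sort=True)
    group_arm = dict(
        df.groupby("practice_id", sort=True)["arm"].first().reset_index().assign(
            code=lambda d: range(len(d))
        )[["code", "arm"]].itertuples(index=False, name=None)
    )
    return Design(X, names, arm_index, X_csc, X_tau, codes, group_arm, dropped)


@dataclass
class FitResult:
    model_kind: str  # two_part | gamma_glm | linear | logistic
    coefficients: pd.Series
    cov: pd.DataFrame = field(repr=False)
    mean_csc: float = np.nan
    mean_tau: float = np.nan
    difference: float = np.nan
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    n: int = 0
    n_boot: int = 0
    notes: list = field(default_factory=list)

    def summary_row(self) -> dict:
        return {
            "model": self.model_kind,
            "mean_csc": self.mean_csc,
            "mean_tau": self.mean_tau,
            "difference": self.difference,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
        }


def _glm_fit(y: np.ndarray, X: np.ndarray, family) -> np.ndarray:
    try:
        res = sm.GLM(y, X, family=family).fit(maxiter=200, tol=1e-9)
    except Exception as exc:  # pragma: no cover - surfaced with context
        raise ConvergenceError(f"GLM fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError("GLM did not converge")
    return np.asarray(res.params)


def _gamma_fit_reduced(y, X):
    """Gamma-log fit that falls back to the intercept+arm design when the
    sample is too small for the full covariate set or the full fit fails.

    Returns (params, n_columns_used); columns 0 and 1 are always the
    intercept and the arm indicator.
    """
    fam = sm.families.Gamma(sm.families.links.Log())
    k = X.shape[1]
    if len(y) >= 3 * k:
        try:
            return _glm_fit(y, X, fam), k
        except ConvergenceError:
            pass
    return _glm_fit(y, X[:, :2], fam), 2


def _expected_two_part(y, X, X_csc, X_tau):
    any_cost = (y > 0).astype(float)
    b_logit = _glm_fit(any_cost, X, sm.families.Binomial())
    pos = y > 0
    b_gamma, k_used = _gamma_fit_reduced(y[pos], X[pos])
    mean_c = float(np.mean(_sigmoid(X_csc @ b_logit) * np.exp(X_csc[:, :k_used] @ b_gamma)))
    mean_t = float(np.mean(_sigmoid(X_tau @ b_logit) * np.exp(X_tau[:, :k_used] @ b_gamma)))
    return mean_c, mean_t


def _expected_gamma(y, X, X_csc, X_tau):
    b, k_used = _gamma_fit_reduced(y, X)
    return (
        float(np.mean(np.exp(X_csc[:, :k_used] @ b))),
        float(np.mean(np.exp(X_tau[:, :k_used] @ b))),
    )


def _expected_linear(y, X, X_csc, X_tau):
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.mean(X_csc @ b)), float(np.mean(X_tau @ b))


def _expected_logistic(y, X, X_csc, X_tau):
    b = _glm_fit(y, X, sm.families.Binomial())
    return float(np.mean(_sigmoid(X_csc @ b))), float(np.mean(_sigmoid(X_tau @ b)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


_EXPECTED = {
    "two_part": _expected_two_part,
    "gamma_glm": _expected_gamma,
    "linear": _expected_linear,
    "logistic": _expected_logistic,
}


def _cluster_bootstrap_se(y, design: Design, kind: str, n_boot: int, seed: int):
    """SE of the adjusted difference by resampling practices within arm.

    The plug-in bootstrap variance of a k-cluster mean is biased by the
    factor (k-1)/k; with few clusters per arm this matters, so the variance
    is rescaled by kbar/(kbar-1) with kbar the mean clusters per arm.
    """
    if n_boot <= 0:
        return np.nan, 0
    rng = np.random.default_rng(seed)
    rows_of = {g: np.flatnonzero(design.groups == g) for g in np.unique(design.groups)}
    arm_groups = {
        arm: [g for g, a in design.group_arm.items() if a == arm] for arm in ("CSC", "TAU")
    }
    fn = _EXPECTED[kind]
    diffs = []
    failures = 0
    for _ in range(n_boot):
        idx_parts = []
        for arm, glist in arm_groups.items():
            if not glist:
                continue
            chosen = rng.choice(glist, size=len(glist), replace=True)
            idx_parts.extend(rows_of[g] for g in chosen)
        idx = np.concatenate(idx_parts)
        try:
            mc, mt = fn(y[idx], design.X[idx], design.X_csc[idx], design.X_tau[idx])
            diffs.append(mc - mt)
        except (ConvergenceError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.1 * n_boot:
        raise ConvergenceError(f"{failures}/{n_boot} bootstrap replicates failed")
    kbar = np.mean([len(g) for g in arm_groups.values() if g])
    small_k = np.sqrt(kbar / (kbar - 1.0)) if kbar > 1 else 1.0
    return float(np.std(diffs, ddof=1) * small_k), len(diffs)


def _cluster_jackknife_se(y, design: Design, kind: str):
    """SE of the adjusted difference by the delete-one-practice jackknife.

    The grouped jackknife has better small-sample behavior than the pairs
    cluster bootstrap for nonlinear recycled-prediction estimators at a few
    dozen clusters, and needs only G refits.
    """
    fn = _EXPECTED[kind]
    groups = np.unique(design.groups)
    if len(groups) < 2:
        return np.nan, 0
    estimates = []
    failures = 0
    for g in groups:
        keep = design.groups != g
        try:
            mc, mt = fn(y[keep], design.X[keep], design.X_csc[keep], design.X_tau[keep])
            estimates.append(mc - mt)
        except (ConvergenceError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.2 * len(groups):
        raise ConvergenceError(f"{failures}/{len(groups)} jackknife refits failed")
    est = np.asarray(estimates)
    G = len(est)
    se = np.sqrt((G - 1) / G * np.sum((est - est.mean()) ** 2))
    return float(se), G


def _difference_se(y, design: Design, kind: str, se_method: str, n_boot: int, seed: int):
    if se_method == "jackknife":
        return _cluster_jackknife_se(y, design, kind)
    if se_method == "bootstrap":
        return _cluster_bootstrap_se(y, design, kind, n_boot, seed)
    if se_method == "none":
        return np.nan, 0
    raise ValueError(f"unknown se_method {se_method!r}")


def _cov_kwds(cov_type: str, groups):
    if cov_type == "cluster":
        return {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
    return {"cov_type": cov_type}


def _robust_fit(y, X, names, cov_type: str, groups):
    res = sm.OLS(y, X).fit(**_cov_kwds(cov_type, groups))
    coefs = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    return coefs, cov


def _reporting_fit(y, X, names, kind: str, cov_type: str, groups):
    """Coefficients + robust covariance of the (main part of the) fitted model.

    For the two-part model this reports the gamma part on positive costs,
    with the logit part noted separately by the caller.
    """
    kwds = _cov_kwds(cov_type, groups)
    if kind == "linear":
        res = sm.OLS(y, X).fit(**kwds)
    elif kind == "logistic":
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(**kwds)
    elif kind == "gamma_glm":
        res = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit(**kwds)
    elif kind == "two_part":
        pos = y > 0
        try:
            res = sm.GLM(y[pos], X[pos], family=sm.families.Gamma(sm.families.links.Log())).fit(
                **(_cov_kwds(cov_type, groups[pos]) if cov_type == "cluster" else kwds)
            )
        except Exception:
            res = sm.GLM(y[pos], X[pos, :2], family=sm.families.Gamma(sm.families.links.Log())).fit(
                **(_cov_kwds(cov_type, groups[pos]) if cov_type == "cluster" else kwds)
            )
            names = names[:2]
    else:  # pragma: no cover
        raise ValueError(kind)
    params = np.asarray(res.params)
    names = names[: len(params)]
    coefs = pd.Series(params, index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    return coefs, cov


def fit_cost_model(
    df: pd.DataFrame,
    outcome: str,
    adjustment: Adjustment | None = None,
    zero_threshold: float = 0.05,
    cov_type: str = "HC1",
    se_method: str = "jackknife",
    n_boot: int = 1000,
    seed: int = 0,
) -> FitResult:
    """Adjusted arm difference in a nonnegative cost outcome.

    Two-part (logit x gamma-log) when the zero fraction is at least
    ``zero_threshold``, single gamma-log GLM otherwise; recycled-prediction
    means.  The difference SE resamples practices: delete-one-practice
    jackknife by default, or a within-arm cluster bootstrap
    (``se_method='bootstrap'`` with ``n_boot`` draws); ``se_method='none'``
    skips it.
    """
    y = df[outcome].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError(f"outcome {outcome!r} contains missing values; impute first")
    if (y < 0).any():
        raise ValueError(f"outcome {outcome!r} must be nonnegative")
    if (y == 0).all():
        raise DegenerateModelError(f"outcome {outcome!r} is identically zero")
    notes = []
    zero_frac = float((y == 0).mean())
    if zero_frac >= zero_threshold:
        kind = "two_part"
    else:
        kind = "gamma_glm"
        if zero_frac > 0:
            eps = 0.5 * y[y > 0].min()
            y = np.where(y == 0, eps, y)
            notes.append(f"replaced {int(zero_frac * len(y))} zeros by {eps:.4g} for the gamma branch")
    design = build_design(df, adjustment)
    if design.dropped:
        notes.append(f"dropped constant predictors: {design.dropped}")
    if np.ptp(y) == 0:
        # constant positive outcome: exact degenerate answer, no model needed
        const = float(y[0])
        coefs = pd.Series(np.zeros(len(design.names)), index=design.names)
        return FitResult(kind, coefs, pd.DataFrame(0.0, index=design.names, columns=design.names),
                         const, const, 0.0, 0.0, 0.0, 0.0, 1.0, len(y), 0, notes)

    fn = _EXPECTED[kind]
    mean_c, mean_t = fn(y, design.X, design.X_csc, design.X_tau)
    diff = mean_c - mean_t
    se, n_done = _difference_se(y, design, kind, se_method, n_boot, seed)
    ci_low, ci_high, p = _wald(diff, se)
    coefs, cov = _reporting_fit(y, design.X, design.names, kind, cov_type, design.groups)
    notes.append(f"zero fraction {zero_frac:.3f}; model {kind}; se {se_method}")
    return FitResult(kind, coefs, cov, mean_c, mean_t, diff, se, ci_low, ci_high, p, len(y), n_done, notes)


def fit_effect_model(
    df: pd.DataFrame,
    outcome: str,
    adjustment: Adjustment | None = None,
    family: str = "auto",
    cov_type: str = "HC1",
    se_method: str = "jackknife",
    n_boot: int = 1000,
    seed: int = 0,
) -> FitResult:
    """Adjusted arm difference in a health effect (QALY, utility, or binary).

    ``family='auto'`` uses a gamma-log GLM for strictly positive outcomes, a
    logistic model for 0/1 outcomes, and a linear model with robust SEs
    otherwise.
    """
    y = df[outcome].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError(f"outcome {outcome!r} contains missing values; impute first")
    if family == "auto":
        uniq = np.unique(y)
        if uniq.size <= 2 and np.isin(uniq, (0.0, 1.0)).all():
            family = "logistic"
        elif (y > 0).all():
            family = "gamma"
        else:
            family = "linear"
    kind = {"gamma": "gamma_glm", "linear": "linear", "logistic": "logistic"}[family]
    design = build_design(df, adjustment)
    notes = list(design.dropped and [f"dropped constant predictors: {design.dropped}"] or [])
    if np.ptp(y) == 0:
        const = float(y[0])
        coefs = pd.Series(np.zeros(len(design.names)), index=design.names)
        return FitResult(kind, coefs, pd.DataFrame(0.0, index=design.names, columns=design.names),
                         const, const, 0.0, 0.0, 0.0, 0.0, 1.0, len(y), 0, notes)
    fn = _EXPECTED[kind]
    mean_c, mean_t = fn(y, design.X, design.X_csc, design.X_tau)
    diff = mean_c - mean_t
    if kind == "linear" and se_method == "analytic":
        # linear recycled difference equals the arm coefficient; analytic SE
        coefs, cov = _robust_fit(y, design.X, design.names, cov_type, design.groups)
        se = float(np.sqrt(cov.iloc[design.arm_index, design.arm_index]))
        ci_low, ci_high, p = _wald(diff, se)
        return FitResult(kind, coefs, cov, mean_c, mean_t, diff, se, ci_low, ci_high, p, len(y), 0, notes)
    se, n_done = _difference_se(y, design, kind, se_method, n_boot, seed)
    ci_low, ci_high, p = _wald(diff, se)
    coefs, cov = _reporting_fit(y, design.X, design.names, kind, cov_type, design.groups)
    return FitResult(kind, coefs, cov, mean_c, mean_t, diff, se, ci_low, ci_high, p, len(y), n_done, notes)


def _wald(diff: float, se: float):
    if not np.isfinite(se) or se == 0:
        return np.nan, np.nan, np.nan
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return diff - Z975 * se, diff + Z975 * se, float(p)


# ---------------------------------------------------------------------------


def baseline_tests(records: pd.DataFrame, variables: list | None = None) -> pd.DataFrame:
    """Arm-comparison p-values for baseline variables.

    Continuous variables: F-test of the arm term from linear regression;
    binary: logistic regression LR test; three or more categories:
    multinomial logistic LR test.  Single-level variables are skipped with a
    note.
    """
    if variables is None:
        variables = [
            c
            for c in records.columns
            if c not in ("patient_id", "practice_id", "arm") and not records[c].isna().all()
        ]
    arm = (records["arm"] == "CSC").to_numpy(float)
    X = np.column_stack([np.ones(len(records)), arm])
    rows = []
    for var in variables:
        s = records[var]
        obs = s.notna().to_numpy()
        note = ""
        p = np.nan
        test = ""
        yv = s[obs]
        nu = yv.nunique()
        if nu < 2:
            rows.append({"variable": var, "test": "skipped", "p_value": np.nan, "note": "single level"})
            continue
        Xo = X[obs]
        try:
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or nu <= max(2, min(6, int(np.sqrt(len(yv))))) and not np.issubdtype(s.dtype, np.floating):
                codes, _ = pd.factorize(yv, sort=True)
                if nu == 2:
                    test = "logistic"
                    full = sm.GLM(codes, Xo, family=sm.families.Binomial()).fit()
                    null = sm.GLM(codes, Xo[:, :1], family=sm.families.Binomial()).fit()
                    lr = 2.0 * (full.llf - null.llf)
                    p = float(stats.chi2.sf(max(lr, 0.0), 1))
                else:
                    test = "multinomial"
                    with np.errstate(all="ignore"):
                        full = sm.MNLogit(codes, Xo).fit(disp=0, maxiter=500, method="bfgs")
                        null = sm.MNLogit(codes, Xo[:, :1]).fit(disp=0, maxiter=500, method="bfgs")
                    lr = 2.0 * (full.llf - null.llf)
                    p = float(stats.chi2.sf(max(lr, 0.0), nu - 1))
            else:
                test = "f_test"
                res = sm.OLS(yv.to_numpy(float), Xo).fit()
                p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
        except Exception as exc:
            note = f"test failed: {type(exc).__name__}"
            p = np.nan
        rows.append({"variable": var, "test": test, "p_value": p, "note": note})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


@dataclass
class PooledResult:
    """Rubin's-rules pooled estimate across m imputations."""

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    m: int
    se: float = field(init=False)
    p_value: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.se = float(np.sqrt(self.total_variance))
        if self.se == 0:
            self.p_value = 1.0 if self.estimate == 0 else 0.0
            self.ci_low = self.ci_high = self.estimate
            return
        t = self.estimate / self.se
        self.p_value = float(2.0 * stats.t.sf(abs(t), self.df))
        q = float(stats.t.ppf(0.975, self.df))
        self.ci_low = self.estimate - q * self.se
        self.ci_high = self.estimate + q * self.se


def pool_rubin(estimates, variances, dfcom: float | None = None) -> PooledResult:
    """Rubin's rules on the estimate scale with Barnard-Rubin degrees of freedom."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or len(q) < 2:
        raise ValueError("need matching 1-d estimates and variances with m >= 2")
    m = len(q)
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    total = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = float(dfcom) if dfcom is not None else np.inf
    else:
        r = (1.0 + 1.0 / m) * b
        df_old = (m - 1) * (1.0 + w / r) ** 2
        if dfcom is None:
            df = df_old
        else:
            lam = r / total
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return PooledResult(qbar, w, b, total, df, m)


def pool_fit_results(results: list, dfcom: float | None = None) -> dict:
    """Pool adjusted differences (Rubin) and average the adjusted means."""
    kinds = {r.model_kind for r in results}
    if len(kinds) != 1:
        raise ValueError(f"cannot pool mismatched model kinds: {sorted(kinds)}")
    pooled = pool_rubin([r.difference for r in results], [r.se**2 for r in results], dfcom=dfcom)
    return {
        "model": results[0].model_kind,
        "mean_csc": float(np.mean([r.mean_csc for r in results])),
        "mean_tau": float(np.mean([r.mean_tau for r in results])),
        "difference": pooled.estimate,
        "se": pooled.se,
        "ci_low": pooled.ci_low,
        "ci_high": pooled.ci_high,
        "p_value": pooled.p_value,
        "pooled": pooled,
    }
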