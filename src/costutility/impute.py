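"""Missing-data strategies: MICE with predictive mean matching, LOCF,
and complete-case filtering.

The main analysis path is multiple imputation by chained equations (MICE)
assuming missing at random, with predictive mean matching (PMM): each
variable with missing cells is regressed on the remaining analysis variables,
regression parameters are drawn from their approximate posterior, and every
missing cell is filled with the *observed* value of one of the k nearest
donors by predicted mean.  Imputed values therefore never leave the observed
support of a variable, which also keeps integer scores and category codes
valid without special casing.  Variables are visited in order of increasing
missingness; m completed copies are produced (default m = 20, donor pool
k = 5, 10 chained iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSet:
    """m completed copies of the analysis dataset plus the model log."""

    datasets: list  # list[pd.DataFrame]
    log: dict = field(repr=False)
    seed: int = 0

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, i):
        return self.datasets[i]

    def write(self, directory) -> None:
        import json
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets):
            df.to_csv(directory / f"imputation_{i:02d}.csv", index=False)
        with open(directory / "imputation_log.json", "w") as fh:
            json.dump({"seed": self.seed, "m": self.m, "log": self.log}, fh, indent=2, default=str)


def _encode_predictors(data: pd.DataFrame, predictor_cols: list) -> tuple:
    """Numeric predictor matrix; object/category columns become dummy blocks."""
    blocks, names = [], []
    for col in predictor_cols:
        s = data[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            blocks.append(dummies.to_numpy())
            names.extend(dummies.columns)
        else:
            blocks.append(s.to_numpy(float)[:, None])
            names.append(col)
    X = np.hstack(blocks) if blocks else np.empty((len(data), 0))
    return X, names


def mice_pmm(
    data: pd.DataFrame,
    variables: list | None = None,
    predictors: list | None = None,
    m: int = 20,
    donors: int = 5,
    iterations: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """Multiple imputation by chained equations with predictive mean matching.

    Parameters
    ----------
    data : analysis dataset (wide, one row per patient).
    variables : columns eligible for imputation (numeric); defaults to all
        numeric columns with at least one missing value.
    predictors : additional fully-observed columns used as predictors in every
        imputation model (covariates; categorical allowed).  All ``variables``
        other than the target always serve as predictors.
    m, donors, iterations, seed : imputation count, donor-pool size, chained
        iterations, random seed (reproducible given identical inputs).
    """
    if m < 2:
        raise ImputationError("m must be >= 2")
    if donors < 1 or iterations < 1:
        raise ImputationError("donors and iterations must be >= 1")
    if variables is None:
        numeric = data.select_dtypes(include=[np.number]).columns
        variables = [c for c in numeric if data[c].isna().any()]
    variables = list(variables)
    for v in variables:
        if data[v].notna().sum() == 0:
            raise ImputationError(f"variable {v!r} has zero observed values")
    predictors = [c for c in (predictors or []) if c not in variables]
    for c in predictors:
        if data[c].isna().any():
            raise ImputationError(f"predictor {c!r} must be fully observed")
    if not predictors and not variables:
        raise ImputationError("no variables to impute and no predictors given")

    X_extra, extra_names = _encode_predictors(data, predictors)
    # constant extra predictors carry no information; drop with a log entry
    dropped = [n for j, n in enumerate(extra_names) if np.ptp(X_extra[:, j]) == 0]
    keep = [j for j, n in enumerate(extra_names) if n not in dropped]
    X_extra = X_extra[:, keep]
    extra_names = [extra_names[j] for j in keep]

    miss_frac = {v: float(data[v].isna().mean()) for v in variables}
    visit_order = sorted((v for v in variables if miss_frac[v] > 0), key=lambda v: miss_frac[v])
    log = {
        "variables": variables,
        "visit_order": visit_order,
        "missing_fraction": miss_frac,
        "predictors": {
            v: [c for c in variables if c != v] + extra_names for v in visit_order
        },
        "dropped_predictors": dropped,
        "m": m,
        "donors": donors,
        "iterations": iterations,
    }

    master = np.column_stack([data[v].to_numpy(float) for v in variables]) if variables else np.empty((len(data), 0))
    miss_mask = np.isnan(master)
    obs_values = {v: data[v].dropna().to_numpy(float) for v in variables}

    child_rngs = np.random.default_rng(seed).spawn(m)
    datasets = []
    for chain_rng in child_rngs:
        filled = master.copy()
        for j, v in enumerate(variables):
            nmiss = miss_mask[:, j].sum()
            if nmiss:
                filled[miss_mask[:, j], j] = chain_rng.choice(obs_values[v], size=nmiss, replace=True)
        for _ in range(iterations):
            for v in visit_order:
                j = variables.index(v)
                _pmm_update(filled, miss_mask, j, X_extra, donors, chain_rng)
        out = data.copy()
        for j, v in enumerate(variables):
            out[v] = filled[:, j]
        datasets.append(out)
    return ImputationSet(datasets=datasets, log=log, seed=seed)


def _pmm_update(
    filled: np.ndarray,
    miss_mask: np.ndarray,
    j: int,
    X_extra: np.ndarray,
    donors: int,
    rng: np.random.Generator,
) -> None:
    """One PMM draw for column j given current completions of the others."""
    n = filled.shape[0]
    obs = ~miss_mask[:, j]
    mis = miss_mask[:, j]
    others = np.delete(filled, j, axis=1)
    X = np.column_stack([np.ones(n), others, X_extra])
    # standardize for numerical stability; ridge guards collinearity
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    y = filled[:, j]

    Xo, yo = Xs[obs], y[obs]
    XtX = Xo.T @ Xo + 1e-6 * np.eye(Xs.shape[1])
    Xty = Xo.T @ yo
    beta_hat = np.linalg.solve(XtX, Xty)
    resid = yo - Xo @ beta_hat
    dof = max(int(obs.sum()) - Xs.shape[1], 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    # posterior draw of beta (approximate Bayesian bootstrap of parameters)
    cov = sigma2 * np.linalg.inv(XtX)
    cov = (cov + cov.T) / 2.0
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    beta_star = beta_hat + L @ rng.standard_normal(cov.shape[0])

    mu_obs = Xo @ beta_hat  # type-1 matching: obs under beta_hat
    mu_mis = Xs[mis] @ beta_star
    k = min(donors, len(yo))
    # k nearest observed donors by predicted mean, one chosen at random
    dist = np.abs(mu_obs[None, :] - mu_mis[:, None])
    nearest = np.argpartition(dist, kth=k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(mu_mis)), rng.integers(0, k, size=len(mu_mis))]
    filled[mis, j] = yo[pick]


# ---------------------------------------------------------------------------


def locf(data: pd.DataFrame) -> pd.DataFrame:
    """Last observation carried forward along the T0 -> T1 -> T2 axis.

    Applies to every longitudinal column triple ``<base>_t0/_t1/_t2`` and
    ``<base>_w0/_w1/_w2``.  Missing baseline values stay missing (forward-only
    rule); such records fall back to complete-case handling downstream.
    """
    out = data.copy()
    for suffixes in (("_t0", "_t1", "_t2"), ("_w0", "_w1", "_w2")):
        bases = {c[: -len(suffixes[0])] for c in out.columns if c.endswith(suffixes[0])}
        for base in sorted(bases):
            cols = [base + s for s in suffixes]
            if all(c in out.columns for c in cols):
                out[cols] = out[cols].ffill(axis=1)
    return out


@dataclass
class CompleteCaseResult:
    data: pd.DataFrame
    n_retained: int
    n_dropped: int


def complete_cases(data: pd.DataFrame, analysis_variables: list) -> CompleteCaseResult:
    """Retain rows fully observed on the analysis variables."""
    if not analysis_variables:
        raise ValueError("analysis_variables must be nonempty")
    missing_cols = [c for c in analysis_variables if c not in data.columns]
    if missing_cols:
        raise KeyError(f"analysis variables not in data: {missing_cols}")
    keep = data[analysis_variables].notna().all(axis=1)
    filtered = data.loc[keep].copy()
    if filtered.empty:
        import warnings

        warnings.warn("complete-case filtering removed every row", stacklevel=2)
    return CompleteCaseResult(data=filtered, n_retained=int(keep.sum()), n_dropped=int((~keep).sum()))
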