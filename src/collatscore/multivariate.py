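"""Multivariate outcome models: OLS regression tables, MANOVA, subgroups.

``fit_ols`` produces the regression-table quantities (coefficients, SEs,
two-sided t tests, standardized β, overall F, R² and adjusted R²) via
ordinary least squares.  ``fit_manova`` tests each predictor — and all
predictors jointly — against a set of outcomes with Pillai's trace and its
standard F approximation; with a single outcome column the joint test
reduces exactly to the OLS overall F.  ``subgroup_filter`` carves clinical
subgroups (territory, infarct-volume band, severity threshold) with a
minimum-n guard: an underpowered subgroup is reported as not analyzable
rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable
from .design import DESIGN_COLUMNS, reporting_design

__all__ = [
    "RegressionFit",
    "ManovaFit",
    "SubgroupSpec",
    "ModelError",
    "fit_ols",
    "fit_manova",
    "subgroup_filter",
    "build_design",
]


class ModelError(ValueError):
    """Model cannot be fitted on the given data (rank, sample size, ...)."""


@dataclass(frozen=True)
class RegressionFit:
    """One fitted linear regression, in reporting-table layout."""

    outcome: str
    predictors: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    beta_std: dict[str, float]
    intercept: Optional[float]
    f_value: float
    df_model: float
    df_resid: float
    f_pvalue: float
    r2: float
    adj_r2: float
    n_used: int

    def table(self) -> pd.DataFrame:
        rows = {
            name: {
                "coef": self.coef[name],
                "se": self.se[name],
                "t": self.t[name],
                "p": self.p[name],
                "beta": self.beta_std[name],
            }
            for name in self.predictors
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "coef": self.coef,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "beta_std": self.beta_std,
            "intercept": self.intercept,
            "f_value": self.f_value,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "f_pvalue": self.f_pvalue,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n_used": self.n_used,
        }


@dataclass(frozen=True)
class ManovaFit:
    """Pillai-trace tests per predictor (plus the joint "omnibus" term)."""

    outcomes: tuple[str, ...]
    terms: dict[str, dict[str, float]]  # name -> pillai, f_value, df1, df2, p
    n_used: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.terms, orient="index")

    def as_dict(self) -> dict:
        return {
            "outcomes": list(self.outcomes),
            "terms": self.terms,
            "n_used": self.n_used,
        }


def _find_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns implicated in a rank deficiency (pivoted-QR heuristic)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_ols(
    y,
    X: pd.DataFrame,
    *,
    intercept: bool = True,
    outcome: Optional[str] = None,
) -> RegressionFit:
    """Ordinary least squares with the reporting-table extras.

    Listwise-deletes incomplete rows, requires ``n > p + 1`` and a
    full-column-rank design, and reports standardized β computed by
    z-scoring the outcome and every predictor (binary predictors included,
    the convention of mainstream statistics packages).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name=outcome or "y")
    data = pd.concat([y, X.astype(float)], axis=1).dropna()
    n, p = data.shape[0], X.shape[1]
    if n <= p + 1:
        raise ModelError(
            f"insufficient data: {n} complete rows for {p} predictors"
        )
    yv = data.iloc[:, 0].to_numpy()
    Xv = data.iloc[:, 1:]
    design = sm.add_constant(Xv, has_constant="add") if intercept else Xv
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        cols = _find_collinear(design.to_numpy(), list(design.columns))
        raise ModelError(f"design matrix is rank deficient; collinear columns: {cols}")
    res = sm.OLS(yv, design).fit()

    names = tuple(Xv.columns)
    sy = yv.std(ddof=1)
    beta = {}
    for name in names:
        sx = Xv[name].to_numpy().std(ddof=1)
        beta[name] = float(res.params[name] * sx / sy) if sy > 0 else np.nan
    return RegressionFit(
        outcome=y.name,
        predictors=names,
        coef={k: float(res.params[k]) for k in names},
        se={k: float(res.bse[k]) for k in names},
        t={k: float(res.tvalues[k]) for k in names},
        p={k: float(res.pvalues[k]) for k in names},
        beta_std=beta,
        intercept=float(res.params["const"]) if intercept else None,
        f_value=float(res.fvalue),
        df_model=float(res.df_model),
        df_resid=float(res.df_resid),
        f_pvalue=float(res.f_pvalue),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n_used=int(n),
    )


def _pillai_f(V: float, p_dv: int, q: int, df_e: int) -> tuple[float, float, float]:
    """Standard F approximation for Pillai's trace.

    ``p_dv`` outcomes, hypothesis rank ``q``, error df ``df_e``.
    """
    s = min(p_dv, q)
    m = (abs(p_dv - q) - 1) / 2.0
    nn = (df_e - p_dv - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    denom = s - V
    if denom <= 0:
        return np.inf, df1, df2
    f = (df2 / df1) * (V / denom)
    return f, df1, df2


def fit_manova(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    *,
    intercept: bool = True,
) -> ManovaFit:
    """Pillai's trace MANOVA of outcomes ``Y`` on predictors ``X``.

    Tests each predictor's coefficient row across all outcomes jointly, and
    all predictors at once under the term ``"omnibus"``.  With a single
    outcome column the omnibus F equals the OLS overall F exactly.
    """
    if not isinstance(Y, pd.DataFrame):
        Y = pd.DataFrame(np.asarray(Y))
        Y.columns = [f"y{i}" for i in range(Y.shape[1])]
    data = pd.concat([Y.astype(float), X.astype(float)], axis=1).dropna()
    p_dv = Y.shape[1]
    Yv = data.iloc[:, :p_dv].to_numpy()
    Xv = data.iloc[:, p_dv:]
    design = sm.add_constant(Xv, has_constant="add") if intercept else Xv
    D = design.to_numpy()
    n, k = D.shape
    rank_x = np.linalg.matrix_rank(D)
    if rank_x < k:
        cols = _find_collinear(D, list(design.columns))
        raise ModelError(f"design matrix is rank deficient; collinear columns: {cols}")
    df_e = n - k
    if df_e < p_dv:
        raise ModelError(f"too few rows ({n}) for {k} predictors and {p_dv} outcomes")

    XtX_inv = np.linalg.inv(D.T @ D)
    B = XtX_inv @ D.T @ Yv
    resid = Yv - D @ B
    E = resid.T @ resid
    # residual covariance must be non-singular for the tests to exist
    if np.linalg.matrix_rank(E) < p_dv:
        raise ModelError(
            "singular residual covariance across outcomes (degenerate or "
            "duplicated outcome columns)"
        )

    names = list(design.columns)
    slope_idx = [i for i, c in enumerate(names) if c != "const"]

    def pillai_term(rows: list[int]) -> dict[str, float]:
        L = np.zeros((len(rows), k))
        for j, i in enumerate(rows):
            L[j, i] = 1.0
        M = L @ XtX_inv @ L.T
        LB = L @ B
        H = LB.T @ np.linalg.solve(M, LB)
        V = float(np.trace(np.linalg.solve((H + E).T, H.T).T))
        f, df1, df2 = _pillai_f(V, p_dv, len(rows), df_e)
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        return {
            "pillai": V,
            "f_value": float(f),
            "df1": float(df1),
            "df2": float(df2),
            "p": p,
        }

    terms = {names[i]: pillai_term([i]) for i in slope_idx}
    terms["omnibus"] = pillai_term(slope_idx)
    return ManovaFit(outcomes=tuple(Y.columns), terms=terms, n_used=int(n))


@dataclass(frozen=True)
class SubgroupSpec:
    """A clinical subgroup: filters plus a minimum-n guard.

    ``combine`` decides whether the FIV band and the NIHSS threshold are
    required jointly (``"all"``) or alternatively (``"any"`` — the malignant
    profile is large infarct *or* severe deficit).  A subgroup smaller than
    ``min_n`` after filtering is flagged not analyzable downstream instead
    of being fitted.
    """

    name: str
    territory: Optional[str] = None
    fiv_min: Optional[float] = None
    fiv_max: Optional[float] = None
    nihss_gt: Optional[float] = None
    combine: Literal["all", "any"] = "all"
    min_n: int = 20

    def __post_init__(self) -> None:
        if self.min_n < len(DESIGN_COLUMNS) + 2:
            raise ValueError(
                f"min_n must be >= number of predictors + 2 "
                f"({len(DESIGN_COLUMNS) + 2}), got {self.min_n}"
            )
        if (
            self.fiv_min is not None
            and self.fiv_max is not None
            and self.fiv_min >= self.fiv_max
        ):
            raise ValueError("fiv_min must be below fiv_max")


def subgroup_filter(cohort: CohortTable, spec: SubgroupSpec) -> CohortTable:
    """Apply a subgroup spec; rows failing any filter (or with a missing
    filter variable) are dropped.  Order is preserved; an empty result is
    allowed — downstream fitting decides analyzability via ``spec.min_n``."""
    df = cohort.table
    mask = np.ones(len(df), dtype=bool)
    if spec.territory is not None:
        mask &= (df["territory"] == spec.territory).to_numpy()
    sev_conditions = []
    if spec.fiv_min is not None or spec.fiv_max is not None:
        fiv = df["fiv_ml"].to_numpy(dtype=float)
        cond = ~np.isnan(fiv)
        if spec.fiv_min is not None:
            cond &= fiv >= spec.fiv_min
        if spec.fiv_max is not None:
            cond &= fiv <= spec.fiv_max
        sev_conditions.append(cond)
    if spec.nihss_gt is not None:
        nihss = df["nihss_discharge"].to_numpy(dtype=float)
        sev_conditions.append(~np.isnan(nihss) & (nihss > spec.nihss_gt))
    if sev_conditions:
        stacked = np.vstack(sev_conditions)
        mask &= stacked.all(axis=0) if spec.combine == "all" else stacked.any(axis=0)
    return cohort.subset(mask)


def build_design(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Reporting design matrix (12 predictors, no intercept column).

    Columns in table order: whole-brain score, pial-only score,
    atherosclerosis, glucose, statin, smoking, infection, age, male sex and
    the three treatment dummies against the "no intervention" reference.
    Rows with any missing predictor are listwise-deleted.
    """
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    return reporting_design(df)
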