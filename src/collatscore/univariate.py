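"""Univariate association screen: Pearson's r and Cramér's V.

Continuous predictors are tested against each (numeric) outcome with
Pearson's product-moment correlation; categorical predictors with a Pearson
χ² test on the contingency table of predictor level × outcome quantile bin,
summarised as Cramér's V.  Missing values are removed pairwise per
association.  Raw two-sided p-values are reported without multiplicity
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "AssociationError",
    "pearson_r",
    "cramers_v",
    "univariate_screen",
]


class AssociationError(ValueError):
    """Degenerate input to an association test."""


@dataclass(frozen=True)
class AssociationResult:
    """One predictor-outcome association."""

    predictor: str
    outcome: str
    kind: Literal["pearson_r", "cramers_v"]
    effect_size: float
    statistic: float  # t for pearson_r, chi2 for cramers_v
    df: float
    p_value: float
    n_used: int

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "kind": self.kind,
            "effect_size": self.effect_size,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "n_used": self.n_used,
        }


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AssociationError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_r(
    x, y, *, predictor: str = "x", outcome: str = "y"
) -> AssociationResult:
    """Pearson correlation with t-test on n-2 degrees of freedom.

    Raises :class:`AssociationError` for fewer than three complete pairs or
    a zero-variance argument (the correlation is undefined there).
    """
    xc, yc = _pairwise_complete(x, y)
    n = xc.size
    if n < 3:
        raise AssociationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        raise AssociationError(
            "zero variance in x or y; correlation undefined"
        )
    r, p = stats.pearsonr(xc, yc)
    r = float(r)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    return AssociationResult(
        predictor=predictor,
        outcome=outcome,
        kind="pearson_r",
        effect_size=r,
        statistic=float(t),
        df=float(df),
        p_value=float(p),
        n_used=int(n),
    )


def cramers_v(
    table, *, predictor: str = "rows", outcome: str = "cols"
) -> AssociationResult:
    """Cramér's V with Pearson χ² (no continuity correction).

    ``V = sqrt(chi2 / (n * (min(r, c) - 1)))`` on an r×c table of
    non-negative counts.  1×k tables and tables with an all-zero margin are
    rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise AssociationError("contingency table must be 2-D")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise AssociationError("contingency table must hold non-negative counts")
    if min(t.shape) < 2:
        raise AssociationError(
            f"Cramér's V undefined for a {t.shape[0]}x{t.shape[1]} table"
        )
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise AssociationError("contingency table has an all-zero row or column")
    n = t.sum()
    if n <= 0:
        raise AssociationError("empty contingency table")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))
    return AssociationResult(
        predictor=predictor,
        outcome=outcome,
        kind="cramers_v",
        effect_size=v,
        statistic=float(chi2),
        df=float(df),
        p_value=float(p),
        n_used=int(n),
    )


def _quantile_bin(y: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin a numeric vector at its interior quantiles (ties merge bins)."""
    qs = np.quantile(y, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    raw = np.searchsorted(edges, y, side="left")
    # ties can strand an empty interior bin; compress to occupied bins only
    _, bins = np.unique(raw, return_inverse=True)
    return bins


def univariate_screen(
    data: pd.DataFrame,
    outcomes: Sequence[str],
    predictors: Mapping[str, Literal["continuous", "categorical"]],
    *,
    n_bins: int = 4,
) -> list[AssociationResult]:
    """Screen every predictor against every outcome.

    Continuous predictors route to :func:`pearson_r`; categorical predictors
    to :func:`cramers_v` on the table of predictor level × outcome quantile
    bin (default quartiles; ties merge bins).  Missing values are deleted
    pairwise per association.  Returns one result per (outcome, predictor)
    pair in the given order.
    """
    if hasattr(data, "table"):  # CohortTable duck-typing
        data = data.table
    results: list[AssociationResult] = []
    for pred, kind in predictors.items():
        if pred not in data.columns:
            raise KeyError(f"unknown predictor column {pred!r}")
        if kind not in ("continuous", "categorical"):
            raise AssociationError(
                f"predictor {pred!r} has unknown type {kind!r}; declare "
                "'continuous' or 'categorical'"
            )
    for outcome in outcomes:
        y_all = pd.to_numeric(data[outcome], errors="raise")
        for pred, kind in predictors.items():
            if kind == "continuous":
                results.append(
                    pearson_r(
                        data[pred].astype(float),
                        y_all.astype(float),
                        predictor=pred,
                        outcome=outcome,
                    )
                )
            else:
                col = data[pred]
                keep = col.notna() & y_all.notna()
                codes, _ = pd.factorize(col[keep], sort=True)
                y = y_all[keep].to_numpy(dtype=float)
                bins = _quantile_bin(y, n_bins)
                n_levels = codes.max() + 1 if codes.size else 0
                n_ybins = bins.max() + 1 if bins.size else 0
                if n_levels < 2 or n_ybins < 2:
                    raise AssociationError(
                        f"{pred!r} vs {outcome!r}: degenerate contingency "
                        f"table ({n_levels} levels x {n_ybins} bins)"
                    )
                table = np.zeros((n_levels, n_ybins), dtype=int)
                np.add.at(table, (codes, bins), 1)
                results.append(
                    cramers_v(table, predictor=pred, outcome=outcome)
                )
    return results


def screen_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Results as a tidy frame (one association per row)."""
    return pd.DataFrame([r.as_dict() for r in results])
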