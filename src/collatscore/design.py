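"""Shared predictor definitions for outcome models.

Two closely related predictor parameterisations are used throughout:

* the *reporting* design (:data:`DESIGN_COLUMNS`): raw whole-brain and
  pial-only scores, binary risk factors, age in years, male sex, and three
  treatment dummies against the "no intervention" reference — the layout of
  the multivariate regression tables;
* the *planted* design (:data:`PLANTED_COLUMNS`): the same predictors with
  the score and age centred and scaled by fixed reference constants, on
  which the synthetic-cohort generator defines its outcome coefficients.

The two differ only by affine transforms of individual columns, so
standardized coefficients agree between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: predictor columns of the reporting design, in table order
DESIGN_COLUMNS: tuple[str, ...] = (
    "whole_brain_score",
    "pial_only_score",
    "atherosclerosis",
    "glucose",
    "statin",
    "smoking",
    "infection",
    "age",
    "male",
    "tx_iv",
    "tx_ia",
    "tx_thrombectomy",
)

#: predictor columns of the planted (generator-side) design
PLANTED_COLUMNS: tuple[str, ...] = (
    "score_z",
    "pial_c",
    "atherosclerosis",
    "glucose",
    "statin",
    "smoking",
    "infection",
    "age_z",
    "male",
    "tx_iv",
    "tx_ia",
    "tx_thrombectomy",
)

TREATMENT_LEVELS: tuple[str, ...] = (
    "none",
    "iv_thrombolysis",
    "ia_thrombolysis",
    "thrombectomy",
)

_TX_DUMMY = {
    "tx_iv": "iv_thrombolysis",
    "tx_ia": "ia_thrombolysis",
    "tx_thrombectomy": "thrombectomy",
}


def treatment_dummies(treatment: pd.Series) -> pd.DataFrame:
    """Dummy-code treatment against the "none" reference.

    Missing treatment records propagate as NaN in every dummy, so they drop
    out under listwise deletion.
    """
    out = pd.DataFrame(index=treatment.index)
    missing = treatment.isna()
    for col, level in _TX_DUMMY.items():
        d = (treatment == level).astype(float)
        d[missing] = np.nan
        out[col] = d
    return out


def reporting_design(df: pd.DataFrame) -> pd.DataFrame:
    """Raw-scale design matrix (no intercept column) from a cohort table.

    Rows with any missing predictor are dropped (listwise deletion).
    """
    required = [
        "whole_brain_score",
        "pial_only_score",
        "atherosclerosis",
        "glucose",
        "statin",
        "smoking",
        "infection",
        "age",
        "male",
        "treatment",
    ]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise KeyError(f"cohort table missing required column(s): {missing_cols}")
    X = pd.DataFrame(index=df.index)
    for col in DESIGN_COLUMNS[:9]:
        X[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    X = pd.concat([X, treatment_dummies(df["treatment"])], axis=1)
    return X.dropna()


def planted_design(
    df: pd.DataFrame,
    score_ref_mean: float,
    score_ref_sd: float,
    age_ref_mean: float,
    age_ref_sd: float,
    pial_center: float = 2.0,
) -> pd.DataFrame:
    """Generator-side design matrix: fixed-reference standardized columns.

    ``score_z = (whole_brain_score - score_ref_mean) / score_ref_sd`` and
    ``age_z = (age - age_ref_mean) / age_ref_sd`` use *fixed* reference
    constants rather than sample moments, so planted coefficients keep the
    same meaning in every realized cohort.
    """
    X = pd.DataFrame(index=df.index)
    X["score_z"] = (df["whole_brain_score"].astype(float) - score_ref_mean) / score_ref_sd
    X["pial_c"] = df["pial_only_score"].astype(float) - pial_center
    for col in ("atherosclerosis", "glucose", "statin", "smoking", "infection"):
        X[col] = df[col].astype(float)
    X["age_z"] = (df["age"].astype(float) - age_ref_mean) / age_ref_sd
    X["male"] = df["male"].astype(float)
    X = pd.concat([X, treatment_dummies(df["treatment"])], axis=1)
    return X
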