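"""Synthetic acute-stroke admission cohorts.

The generator emulates a consecutive emergency-department stroke cohort:
admissions with exclusion flags (imaging/data quality, alternative
diagnosis), demographics and vascular risk factors drawn from configured
marginals, a complete CT-angiography collateral grading sheet per patient,
and three discharge outcomes — final infarct volume (FIV, ml), NIHSS and
mRS.

Generative chain (each arrow a documented, configurable mechanism)::

    risk factors ──> latent atherosclerotic burden ──> vessel grades
                                                       │
                  whole-brain collateral score  <──────┘
                         │
    log1p(FIV) = α₀ + Σ βⱼ xⱼ + shared u + ε          (linear, recoverable)
    severity   = Σ γⱼ xⱼ + shared u + ε  ──monotone──> NIHSS, mRS bins

Effects are planted directly on the standardized whole-brain score (and the
other design predictors), which makes parameter recovery by ordinary least
squares well-posed.  TIA reclassifications carry a near-zero FIV point mass
and mild discharge outcomes, outside the linear FIV model.  Treatment
assignment depends mildly on collateral status (worse collaterals → more
intervention), mimicking confounding by indication while remaining a
function of modelled predictors only.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit, ndtri
from scipy.stats import truncnorm

from . import grading
from .design import PLANTED_COLUMNS, planted_design

logger = logging.getLogger(__name__)

__all__ = [
    "EffectBlock",
    "GeneratorConfig",
    "CohortTable",
    "generate_admissions",
    "apply_exclusions",
    "generate_vasculature",
    "planted_design_for",
]

# interpolation endpoints for the per-slot grade distribution over the full
# code set (-4..1): a near-normal vasculature vs a heavily diseased one
_GRADE_CODES = np.arange(-4, 2)
_HEALTHY_PMF = np.array([0.002, 0.005, 0.010, 0.030, 0.013, 0.940])
_DISEASED_PMF = np.array([0.10, 0.14, 0.16, 0.22, 0.12, 0.26])

# accessory-vessel assessability and pial visibility also degrade with burden
_ASSESS_P0, _ASSESS_SLOPE = 0.97, 0.50
_PIAL_CORT_LAM0, _PIAL_CORT_SLOPE = 12.5, 11.0
_PIAL_CEREB_LAM0, _PIAL_CEREB_SLOPE = 3.8, 3.5

_N_GRADED_SLOTS = 24  # paired graded (22) + midline (2), in grading.SLOTS order
_N_ASSESS_SLOTS = 10

_SLOT_WEIGHTS_VEC = np.array(
    [grading.SLOT_WEIGHTS[slot] for slot in grading.SLOTS], dtype=float
)

EXCLUSION_REASONS = ("data_quality", "alternative_diagnosis")


class EffectBlock(BaseModel):
    """Planted outcome effects on the generator-side design columns.

    ``fiv`` holds coefficients of ``log1p(FIV)`` on the planted design
    (units: log-ml per predictor unit; the score enters per reference SD).
    ``severity`` holds loadings of the shared latent severity driving the
    NIHSS and mRS bins.  Coefficients for omitted predictors are zero.
    """

    model_config = ConfigDict(extra="forbid")

    fiv_intercept: float = 1.539
    fiv: dict[str, float] = Field(
        default_factory=lambda: {
            "score_z": -1.40,
            "pial_c": -0.15,
            "atherosclerosis": 0.25,
            "glucose": 0.35,
            "age_z": 0.10,
            "tx_iv": 0.30,
            "tx_ia": 1.20,
            "tx_thrombectomy": 0.90,
        }
    )
    fiv_shared: float = 1.60
    fiv_resid_sd: float = 2.20
    severity: dict[str, float] = Field(
        default_factory=lambda: {
            "score_z": -0.55,
            "atherosclerosis": 0.30,
            "glucose": 0.45,
            "age_z": 0.25,
        }
    )
    severity_shared: float = 0.70
    severity_resid_sd: float = 0.65
    outcome_noise_sd: float = 0.70

    @model_validator(mode="after")
    def _check(self) -> "EffectBlock":
        for name in ("fiv_resid_sd", "severity_resid_sd", "outcome_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for label, coefs in (("fiv", self.fiv), ("severity", self.severity)):
            unknown = set(coefs) - set(PLANTED_COLUMNS)
            if unknown:
                raise ValueError(
                    f"{label} effect keys not in the planted design: {sorted(unknown)}"
                )
        return self

    @classmethod
    def null(cls) -> "EffectBlock":
        """Zero-effect block: outcomes independent of every predictor."""
        return cls(fiv_intercept=1.90, fiv={}, severity={})

    def coef_vector(self, which: str) -> pd.Series:
        coefs = self.fiv if which == "fiv" else self.severity
        return pd.Series({c: coefs.get(c, 0.0) for c in PLANTED_COLUMNS})


class BurdenModel(BaseModel):
    """Latent atherosclerotic-burden model: burden = expit(linear predictor)."""

    model_config = ConfigDict(extra="forbid")

    intercept: float = -1.10
    atherosclerosis: float = 0.90
    smoking: float = 0.50
    glucose: float = 0.60
    age: float = 0.40  # per reference SD of age
    noise_sd: float = 0.40


class GeneratorConfig(BaseModel):
    """Study-design parameters of the synthetic admission cohort.

    Defaults mirror the emulated cohort: 686 admissions of which 69 are
    excluded for data quality and 87 for an alternative diagnosis (analysis
    set 530); age 65.7 ± 15.0 years truncated to 19-90; 60.9% male; risk
    factor prevalences (atherosclerosis 33%, smoking 39.1%, elevated
    glucose 5.3%, infection 2.5%); treatment mix 32.2% IV thrombolysis,
    6% IA thrombolysis (± bridging), 2% thrombectomy, 55.1% none — the
    remaining 4.7% carry a missing treatment record; 91/530 ≈ 17.2% TIA
    reclassifications; 16.4% unknown symptom onset.
    """

    model_config = ConfigDict(extra="forbid")

    n_admissions: int = 686
    n_excluded_data_quality: int = 69
    n_excluded_alternative_diagnosis: int = 87

    age_mean: float = 65.7
    age_sd: float = 15.0
    age_min: float = 19.0
    age_max: float = 90.0
    male_fraction: float = 0.609

    prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "atherosclerosis": 0.33,
            "smoking": 0.391,
            "glucose": 0.053,
            "infection": 0.025,
            "statin": 0.25,
        }
    )
    treatment_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "iv_thrombolysis": 0.322,
            "ia_thrombolysis": 0.06,
            "thrombectomy": 0.02,
            "none": 0.551,
        }
    )
    territory_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "MCA": 0.64,
            "PCA": 0.10,
            "vertebrobasilar": 0.14,
            "ACA": 0.04,
            "other": 0.08,
        }
    )
    tia_fraction: float = 0.172
    onset_unknown_fraction: float = 0.164

    #: pull of poor collateral status toward intervention (0 = random mix)
    treatment_severity_strength: float = 0.5
    #: pull of good collateral status toward TIA reclassification
    tia_severity_strength: float = 0.8

    burden: BurdenModel = Field(default_factory=BurdenModel)
    effects: EffectBlock = Field(default_factory=EffectBlock)

    # fixed reference constants for the standardized score / latent severity
    score_ref_mean: float = 16.0
    score_ref_sd: float = 20.0
    severity_ref_mean: float = 0.17
    severity_ref_sd: float = 1.25

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        n_excl = self.n_excluded_data_quality + self.n_excluded_alternative_diagnosis
        if self.n_admissions < n_excl:
            raise ValueError(
                f"n_admissions ({self.n_admissions}) smaller than total "
                f"exclusions ({n_excl})"
            )
        probs = {
            "male_fraction": self.male_fraction,
            "tia_fraction": self.tia_fraction,
            "onset_unknown_fraction": self.onset_unknown_fraction,
            **{f"prevalence[{k}]": v for k, v in self.prevalence.items()},
            **{f"treatment_probs[{k}]": v for k, v in self.treatment_probs.items()},
            **{f"territory_probs[{k}]": v for k, v in self.territory_probs.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        missing = set(("atherosclerosis", "smoking", "glucose", "infection", "statin")) - set(
            self.prevalence
        )
        if missing:
            raise ValueError(f"prevalence missing entries: {sorted(missing)}")
        tx_total = sum(self.treatment_probs.values())
        if tx_total > 1.0 + 1e-9 or tx_total <= 0:
            raise ValueError(
                f"treatment probabilities must sum to at most 1 (remainder is "
                f"recorded as missing treatment), got {tx_total}"
            )
        if abs(sum(self.territory_probs.values()) - 1.0) > 1e-9:
            raise ValueError("territory probabilities must sum to 1")
        if self.age_min >= self.age_max or self.age_sd <= 0:
            raise ValueError("invalid age distribution parameters")
        if self.score_ref_sd <= 0 or self.severity_ref_sd <= 0:
            raise ValueError("reference SDs must be > 0")
        return self

    @property
    def treatment_missing_prob(self) -> float:
        return max(0.0, 1.0 - sum(self.treatment_probs.values()))

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """Config with every predictor-outcome dependence removed.

        Planted outcome effects, the severity pull on treatment assignment
        and the collateral-status pull on TIA reclassification are all
        zeroed, so every screen predictor is exactly independent of every
        outcome — the reference condition for type-I-error studies.
        """
        overrides.setdefault("effects", EffectBlock.null())
        overrides.setdefault("treatment_severity_strength", 0.0)
        overrides.setdefault("tia_severity_strength", 0.0)
        return cls(**overrides)

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


@dataclass
class CohortTable:
    """One row per admitted patient, plus the aligned grade matrix.

    ``table`` holds covariates, scores and outcomes; ``grades`` is the
    ``(n, 34)`` integer matrix of vessel grades in canonical slot order
    (``grading.SLOTS``), row-aligned with ``table``.
    """

    table: pd.DataFrame
    grades: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.table["patient_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate patient_id in cohort: {dup!r}")
        if self.grades is not None and len(self.grades) != len(self.table):
            raise ValueError("grade matrix not aligned with cohort table")

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        mask = np.asarray(mask, dtype=bool)
        grades = self.grades[mask] if self.grades is not None else None
        return CohortTable(
            self.table.loc[mask].reset_index(drop=True),
            grades,
            dict(self.provenance),
        )

    def patient_vasculature(self, row: int) -> grading.PatientVasculature:
        """Reconstruct the full grading sheet of one patient row."""
        if self.grades is None:
            raise ValueError("cohort carries no grade matrix")
        rec = self.table.iloc[row]
        return grading.sheet_from_codes(
            self.grades[row],
            grading.PialCounts(
                int(rec["pial_cortical_count"]), int(rec["pial_cerebellar_count"])
            ),
        )

    def vasculature_frame(self) -> pd.DataFrame:
        """Long-format grading sheet: patient_id, vessel, side, grade + pial counts."""
        if self.grades is None:
            raise ValueError("cohort carries no grade matrix")
        n = len(self.table)
        n_slots = len(grading.SLOTS)
        vessels = [v.value for v, _ in grading.SLOTS]
        sides = [s.value for _, s in grading.SLOTS]
        return pd.DataFrame(
            {
                "patient_id": np.repeat(self.table["patient_id"].to_numpy(), n_slots),
                "vessel": np.tile(vessels, n),
                "side": np.tile(sides, n),
                "grade": self.grades.reshape(-1),
                "pial_cortical_count": np.repeat(
                    self.table["pial_cortical_count"].to_numpy(), n_slots
                ),
                "pial_cerebellar_count": np.repeat(
                    self.table["pial_cerebellar_count"].to_numpy(), n_slots
                ),
            }
        )


def _sample_vasculature_batch(
    burden: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (grades (n,34), cortical counts, cerebellar counts)."""
    burden = np.asarray(burden, dtype=float)
    n = burden.shape[0]
    pmf = (1.0 - burden)[:, None] * _HEALTHY_PMF + burden[:, None] * _DISEASED_PMF
    cum = np.cumsum(pmf, axis=1)
    u = rng.random((n, _N_GRADED_SLOTS))
    idx = np.sum(u[:, :, None] >= cum[:, None, :], axis=2)
    graded = _GRADE_CODES[np.minimum(idx, len(_GRADE_CODES) - 1)]
    p_assess = np.clip(_ASSESS_P0 - _ASSESS_SLOPE * burden, 0.0, 1.0)
    assess = (rng.random((n, _N_ASSESS_SLOTS)) < p_assess[:, None]).astype(int)
    grades = np.concatenate([graded, assess], axis=1)
    lam_c = np.clip(_PIAL_CORT_LAM0 - _PIAL_CORT_SLOPE * burden, 0.05, None)
    lam_b = np.clip(_PIAL_CEREB_LAM0 - _PIAL_CEREB_SLOPE * burden, 0.05, None)
    cortical = rng.poisson(lam_c)
    cerebellar = rng.poisson(lam_b)
    return grades, cortical, cerebellar


def _pial_score_arrays(
    cortical: np.ndarray, cerebellar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    cort = np.where(cortical <= 8, 0, np.where(cortical <= 11, 1, 2))
    cereb = np.where(cerebellar == 0, 0, np.where(cerebellar < 3, 1, 2))
    return cort, cereb


def _scores_from_grades(
    grades: np.ndarray, cortical: np.ndarray, cerebellar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized whole-brain and pial-only scores (agrees with `grading`)."""
    cort, cereb = _pial_score_arrays(cortical, cerebellar)
    whole = grades @ _SLOT_WEIGHTS_VEC + cort + cereb
    return whole.astype(int), (cort + cereb).astype(int)


def generate_vasculature(
    burden: float, rng: np.random.Generator
) -> grading.PatientVasculature:
    """Sample one complete grading sheet at a given latent burden in [0, 1].

    Higher burden shifts vessel grades toward stenosis/occlusion, reduces
    accessory-vessel assessability and thins the pial collaterals; the
    expected whole-brain score is strictly decreasing in burden.
    """
    if not 0.0 <= burden <= 1.0:
        raise ValueError(f"burden must lie in [0, 1], got {burden}")
    grades, cortical, cerebellar = _sample_vasculature_batch(
        np.array([float(burden)]), rng
    )
    return grading.sheet_from_codes(
        grades[0], grading.PialCounts(int(cortical[0]), int(cerebellar[0]))
    )


def planted_design_for(cohort: CohortTable | pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """The generator-side design matrix for a cohort, using the config's
    fixed reference constants (see :func:`collatscore.design.planted_design`)."""
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    return planted_design(
        df,
        score_ref_mean=config.score_ref_mean,
        score_ref_sd=config.score_ref_sd,
        age_ref_mean=config.age_mean,
        age_ref_sd=config.age_sd,
    )


def generate_admissions(config: GeneratorConfig, seed: int) -> CohortTable:
    """Generate a full admission cohort (including to-be-excluded records).

    Reproducible: identical (config, seed) pairs yield identical cohorts.
    The seed is mandatory; there is no silent global-state fallback.
    """
    if seed is None:
        raise ValueError("a seed is required; refusing nondeterministic generation")
    if not isinstance(config, GeneratorConfig):
        raise TypeError("config must be a GeneratorConfig")
    rng = np.random.default_rng(int(seed))
    n = config.n_admissions

    # --- exclusion flags: exactly the configured counts -------------------
    excl = np.array(["none"] * n, dtype=object)
    perm = rng.permutation(n)
    n_dq = config.n_excluded_data_quality
    n_ad = config.n_excluded_alternative_diagnosis
    excl[perm[:n_dq]] = "data_quality"
    excl[perm[n_dq : n_dq + n_ad]] = "alternative_diagnosis"

    # --- demographics and risk factors ------------------------------------
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    male = rng.random(n) < config.male_fraction
    prev = config.prevalence
    athero = rng.random(n) < prev["atherosclerosis"]
    smoking = rng.random(n) < prev["smoking"]
    glucose = rng.random(n) < prev["glucose"]
    infection = rng.random(n) < prev["infection"]
    statin = rng.random(n) < prev["statin"]
    territories = list(config.territory_probs)
    territory = rng.choice(
        territories, size=n, p=[config.territory_probs[t] for t in territories]
    )
    onset_known = rng.random(n) >= config.onset_unknown_fraction

    # --- latent burden -> vasculature -> collateral scores -----------------
    age_z = (age - config.age_mean) / config.age_sd
    bm = config.burden
    burden_lin = (
        bm.intercept
        + bm.atherosclerosis * athero
        + bm.smoking * smoking
        + bm.glucose * glucose
        + bm.age * age_z
        + bm.noise_sd * rng.standard_normal(n)
    )
    burden = expit(burden_lin)
    grades, cortical, cerebellar = _sample_vasculature_batch(burden, rng)
    whole_score, pial_only = _scores_from_grades(grades, cortical, cerebellar)
    score_z = (whole_score - config.score_ref_mean) / config.score_ref_sd

    # --- TIA reclassification (better collaterals -> more likely TIA) ------
    s_tia = config.tia_severity_strength
    tia_prop = s_tia * score_z + rng.standard_normal(n)
    tia_cut = np.sqrt(1.0 + s_tia**2) * ndtri(1.0 - config.tia_fraction)
    tia = tia_prop > tia_cut

    # --- treatment assignment (severity-ordered categories) ----------------
    s_tx = config.treatment_severity_strength
    tx_prop = -s_tx * score_z + rng.standard_normal(n)
    u_tx = _std_normal_cdf(tx_prop / np.sqrt(1.0 + s_tx**2))
    tx_order = ["none", np.nan, "iv_thrombolysis", "ia_thrombolysis", "thrombectomy"]
    tx_probs = [
        config.treatment_probs["none"],
        config.treatment_missing_prob,
        config.treatment_probs["iv_thrombolysis"],
        config.treatment_probs["ia_thrombolysis"],
        config.treatment_probs["thrombectomy"],
    ]
    edges = np.cumsum(tx_probs)[:-1]
    tx_idx = np.searchsorted(edges, u_tx, side="right")
    treatment = np.array([tx_order[i] for i in tx_idx], dtype=object)

    # --- outcomes ----------------------------------------------------------
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "excluded": excl,
            "tia": tia.astype(int),
            "age": age,
            "male": male.astype(int),
            "atherosclerosis": athero.astype(int),
            "smoking": smoking.astype(int),
            "glucose": glucose.astype(int),
            "infection": infection.astype(int),
            "statin": statin.astype(int),
            "treatment": treatment,
            "territory": territory,
            "onset_known": onset_known.astype(int),
            "whole_brain_score": whole_score,
            "pial_only_score": pial_only,
            "pial_cortical_count": cortical,
            "pial_cerebellar_count": cerebellar,
        }
    )
    X = planted_design_for(df, config)
    # missing treatment rows: planted treatment effect contributes 0 there
    X_filled = X.fillna(0.0).to_numpy()
    eff = config.effects
    u_shared = rng.standard_normal(n)

    # lognormal FIV keeps volumes strictly positive, so log(FIV) is exactly
    # the planted linear model and OLS recovery is unbiased
    lp_fiv = eff.fiv_intercept + X_filled @ eff.coef_vector("fiv").to_numpy()
    log_fiv = lp_fiv + eff.fiv_shared * u_shared + eff.fiv_resid_sd * rng.standard_normal(n)
    fiv = np.exp(log_fiv)
    fiv_tia = rng.exponential(0.25, size=n)  # drawn for all, applied to TIA rows
    fiv = np.where(tia, fiv_tia, fiv)

    sev_raw = (
        X_filled @ eff.coef_vector("severity").to_numpy()
        + eff.severity_shared * u_shared
        + eff.severity_resid_sd * rng.standard_normal(n)
    )
    sev_z = (sev_raw - config.severity_ref_mean) / config.severity_ref_sd
    w = eff.outcome_noise_sd
    z_nihss = (sev_z + w * rng.standard_normal(n)) / np.sqrt(1.0 + w**2)
    z_mrs = (sev_z + w * rng.standard_normal(n)) / np.sqrt(1.0 + w**2)
    z_adm = (sev_z + 0.6 * rng.standard_normal(n)) / np.sqrt(1.36)

    nihss_adm = np.clip(np.round(np.expm1(1.95 + 0.8 * z_adm)), 0, 42)
    nihss_dis = np.clip(np.round(np.expm1(0.70 + 0.8 * z_nihss)), 0, 42)
    mrs_edges = np.array([-1.00, -0.35, 0.55, 1.10, 1.60, 2.20])
    mrs_adm = np.searchsorted(mrs_edges - 0.80, z_adm, side="right")
    mrs_dis = np.searchsorted(mrs_edges, z_mrs, side="right")

    # TIA reclassifications resolve: near-zero infarct, mild discharge state
    tia_nihss = (rng.random(n) < 0.15).astype(int)
    tia_mrs = (rng.random(n) < 0.30).astype(int)
    nihss_dis = np.where(tia, tia_nihss, nihss_dis)
    mrs_dis = np.where(tia, tia_mrs, mrs_dis)

    df["fiv_ml"] = fiv
    df["nihss_admission"] = nihss_adm.astype(float)
    df["nihss_discharge"] = nihss_dis.astype(float)
    df["mrs_admission"] = mrs_adm.astype(float)
    df["mrs_discharge"] = mrs_dis.astype(float)

    # excluded admissions never complete the outcome work-up
    excluded_mask = excl != "none"
    for col in ("fiv_ml", "nihss_admission", "nihss_discharge", "mrs_admission", "mrs_discharge"):
        df.loc[excluded_mask, col] = np.nan

    provenance = {"seed": int(seed), "config_hash": config.config_hash()}
    return CohortTable(df, grades, provenance)


def _std_normal_cdf(x: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(x)


def apply_exclusions(cohort: CohortTable) -> CohortTable:
    """Drop flagged admissions, preserving order; removal counts go to
    ``provenance['exclusions_removed']`` and the module log."""
    flags = cohort.table["excluded"]
    removed = {reason: int((flags == reason).sum()) for reason in EXCLUSION_REASONS}
    removed["total"] = sum(removed[r] for r in EXCLUSION_REASONS)
    kept = cohort.subset((flags == "none").to_numpy())
    kept.provenance["exclusions_removed"] = removed
    kept.provenance["n_admissions"] = len(cohort)
    kept.provenance["n_analysis"] = len(kept)
    logger.info(
        "exclusions: %d admissions -> %d analysis records (removed %s)",
        len(cohort),
        len(kept),
        removed,
    )
    if len(kept) == 0:
        logger.warning("exclusion stage removed every record")
    return kept
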