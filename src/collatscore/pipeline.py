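"""End-to-end analysis runs: simulate → score → screen → model → report.

A run is fully determined by a :class:`RunConfig` (generator config or an
existing cohort CSV, subgroup specs, model options, seed): the same config
and seed produce byte-identical report files.  Every configured subgroup
appears in the report exactly once — either with fitted models or with a
"not analyzable (n too small)" record, mirroring how severely underpowered
subgroups are reported rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, io
from .cohort import CohortTable, GeneratorConfig, apply_exclusions, generate_admissions
from .multivariate import (
    ManovaFit,
    ModelError,
    RegressionFit,
    SubgroupSpec,
    build_design,
    fit_manova,
    fit_ols,
    subgroup_filter,
)
from .univariate import univariate_screen

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "run_pipeline",
    "render_report",
    "default_subgroups",
    "DEFAULT_UNIVARIATE_PREDICTORS",
    "OUTCOME_COLUMNS",
]

OUTCOME_COLUMNS = ("fiv_ml", "nihss_discharge", "mrs_discharge")

#: Table-3-style screen: predictor -> declared type
DEFAULT_UNIVARIATE_PREDICTORS: dict[str, str] = {
    "atherosclerosis": "categorical",
    "infection": "categorical",
    "glucose": "categorical",
    "statin": "categorical",
    "male": "categorical",
    "smoking": "categorical",
    "age": "continuous",
    "whole_brain_score": "continuous",
    "pial_only_score": "continuous",
    "nihss_admission": "continuous",
    "treatment": "categorical",
}

#: subgroups screened univariately and with MANOVA (full regression runs on all)
_SCREENED_SUBGROUPS = ("all_patients", "mca_only")


def default_subgroups() -> list[SubgroupSpec]:
    """All patients; MCA territory; medium-volume (15-100 ml); malignant
    profile (FIV > 100 ml and/or NIHSS > 17)."""
    return [
        SubgroupSpec("all_patients"),
        SubgroupSpec("mca_only", territory="MCA"),
        SubgroupSpec("medium_fiv", fiv_min=15.0, fiv_max=100.0),
        SubgroupSpec("malignant", fiv_min=100.0, nihss_gt=17.0, combine="any"),
    ]


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    seed: int
    generator: Optional[GeneratorConfig] = None
    cohort_path: Optional[str] = None
    vasculature_path: Optional[str] = None
    subgroups: list[SubgroupSpec] = field(default_factory=default_subgroups)
    fiv_transform: str = "log1p"  # or "raw"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.cohort_path is None):
            raise ValueError(
                "exactly one of generator config and cohort_path must be given"
            )
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.fiv_transform not in ("log1p", "raw"):
            raise ValueError(f"unknown fiv_transform {self.fiv_transform!r}")
        names = [s.name for s in self.subgroups]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate subgroup names: {names}")

    def config_hash(self) -> str:
        payload = {
            "generator": self.generator.model_dump() if self.generator else None,
            "cohort_path": self.cohort_path,
            "subgroups": [dataclasses.asdict(s) for s in self.subgroups],
            "fiv_transform": self.fiv_transform,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All run outputs plus provenance, serializable to stable JSON."""

    summary: dict
    inter_outcome_corr: dict
    univariate: dict
    regressions: dict
    manova: dict
    subgroup_n: dict
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "summary": self.summary,
            "inter_outcome_corr": self.inter_outcome_corr,
            "univariate": self.univariate,
            "regressions": self.regressions,
            "manova": self.manova,
            "subgroup_n": self.subgroup_n,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True, indent=2) + "\n"


def _fiv_outcome(df: pd.DataFrame, transform: str) -> pd.Series:
    fiv = df["fiv_ml"].astype(float)
    if transform == "log1p":
        return np.log1p(fiv).rename("log1p_fiv")
    return fiv.rename("fiv_ml")


def _cohort_summary(cohort: CohortTable, analysis: CohortTable) -> dict:
    df = analysis.table
    fiv = df["fiv_ml"].dropna()
    bands = {
        "lt_15_ml": float((fiv < 15).mean()),
        "15_50_ml": float(((fiv >= 15) & (fiv < 50)).mean()),
        "50_100_ml": float(((fiv >= 50) & (fiv < 100)).mean()),
        "gt_100_ml": float((fiv >= 100).mean()),
    }
    treatment_counts = (
        df["treatment"].value_counts(dropna=False).rename(lambda x: "missing" if pd.isna(x) else x)
    )
    return {
        "n_admissions": len(cohort),
        "n_analysis": len(df),
        "exclusions_removed": analysis.provenance.get("exclusions_removed", {}),
        "age_mean": float(df["age"].mean()),
        "age_sd": float(df["age"].std(ddof=1)),
        "male_fraction": float(df["male"].mean()),
        "prevalence": {
            k: float(df[k].mean())
            for k in ("atherosclerosis", "smoking", "glucose", "infection", "statin")
        },
        "treatment_counts": {str(k): int(v) for k, v in treatment_counts.items()},
        "tia_n": int(df["tia"].sum()),
        "fiv_median_ml": float(fiv.median()),
        "fiv_bands": bands,
        "outcome_medians": {
            c: float(df[c].median())
            for c in ("nihss_admission", "nihss_discharge", "mrs_admission", "mrs_discharge")
        },
    }


def _inter_outcome_corr(df: pd.DataFrame, fiv_t: pd.Series) -> dict:
    pairs = {
        "mrs_vs_nihss": ("mrs_discharge", "nihss_discharge"),
        "mrs_vs_fiv": ("mrs_discharge", None),
        "nihss_vs_fiv": ("nihss_discharge", None),
    }
    out = {}
    for name, (a, b) in pairs.items():
        x = df[a].astype(float)
        y = fiv_t if b is None else df[b].astype(float)
        out[name] = float(x.corr(y))
    return out


def _fit_or_skip(
    sub: CohortTable, spec: SubgroupSpec, outcome: pd.Series, alpha: float
) -> dict:
    X = build_design(sub)
    joined = pd.concat([outcome, X], axis=1).dropna()
    n = len(joined)
    if n < spec.min_n:
        return {"skipped": f"not analyzable (n too small: {n} < {spec.min_n})", "n_used": n}
    try:
        fit = fit_ols(
            joined.iloc[:, 0], joined.iloc[:, 1:], outcome=str(outcome.name)
        )
    except ModelError as exc:
        return {"skipped": f"not analyzable ({exc})", "n_used": n}
    return fit.as_dict()


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> AnalysisReport:
    """Execute all stages; deterministic given (config, seed).

    With ``outdir`` set, writes cohort.csv, vasculature.csv (when grades are
    available), provenance.json, report.json and report.md.
    """
    stage = "load"
    try:
        if config.generator is not None:
            stage = "simulate"
            cohort = generate_admissions(config.generator, config.seed)
        else:
            cohort = io.read_cohort_csv(config.cohort_path, config.vasculature_path)
        stage = "exclusions"
        analysis = apply_exclusions(cohort)
        df = analysis.table
        fiv_t = _fiv_outcome(df, config.fiv_transform)
        outcome_frame = pd.concat(
            [fiv_t, df["nihss_discharge"], df["mrs_discharge"]], axis=1
        )

        stage = "screen"
        univariate: dict[str, dict] = {}
        subgroup_n: dict[str, int] = {}
        subs: dict[str, CohortTable] = {}
        for spec in config.subgroups:
            sub = subgroup_filter(analysis, spec)
            subs[spec.name] = sub
            subgroup_n[spec.name] = len(sub)
        for name in _SCREENED_SUBGROUPS:
            if name not in subs:
                continue
            sub = subs[name]
            if len(sub) < 3:
                univariate[name] = {"skipped": f"not analyzable (n too small: {len(sub)})"}
                continue
            sdf = sub.table.copy()
            screen_df = sdf.assign(
                **{str(fiv_t.name): _fiv_outcome(sdf, config.fiv_transform)}
            )
            results = univariate_screen(
                screen_df,
                [str(fiv_t.name), "nihss_discharge", "mrs_discharge"],
                DEFAULT_UNIVARIATE_PREDICTORS,
            )
            univariate[name] = {"associations": [r.as_dict() for r in results]}

        stage = "regression"
        regressions: dict[str, dict] = {}
        for spec in config.subgroups:
            sub = subs[spec.name]
            sub_fiv = _fiv_outcome(sub.table, config.fiv_transform)
            per_outcome = {}
            for out_name, series in (
                (str(sub_fiv.name), sub_fiv),
                ("nihss_discharge", sub.table["nihss_discharge"].astype(float)),
                ("mrs_discharge", sub.table["mrs_discharge"].astype(float)),
            ):
                per_outcome[out_name] = _fit_or_skip(sub, spec, series, config.alpha)
            regressions[spec.name] = per_outcome

        stage = "manova"
        manova: dict[str, dict] = {}
        for name in _SCREENED_SUBGROUPS:
            if name not in subs:
                continue
            sub = subs[name]
            spec = next(s for s in config.subgroups if s.name == name)
            Y = pd.concat(
                [
                    _fiv_outcome(sub.table, config.fiv_transform),
                    sub.table["nihss_discharge"].astype(float),
                    sub.table["mrs_discharge"].astype(float),
                ],
                axis=1,
            )
            X = build_design(sub)
            joined = pd.concat([Y, X], axis=1).dropna()
            if len(joined) < spec.min_n:
                manova[name] = {
                    "skipped": f"not analyzable (n too small: {len(joined)} < {spec.min_n})"
                }
                continue
            try:
                fit = fit_manova(joined.iloc[:, : Y.shape[1]], joined.iloc[:, Y.shape[1]:])
                manova[name] = fit.as_dict()
            except ModelError as exc:
                manova[name] = {"skipped": f"not analyzable ({exc})"}

        stage = "report"
        report = AnalysisReport(
            summary=_cohort_summary(cohort, analysis),
            inter_outcome_corr=_inter_outcome_corr(df, fiv_t),
            univariate=univariate,
            regressions=regressions,
            manova=manova,
            subgroup_n=subgroup_n,
            provenance={
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "package_version": __version__,
                "fiv_transform": config.fiv_transform,
                "alpha": config.alpha,
                "n_stages": {
                    "admissions": len(cohort),
                    "analysis": len(analysis),
                    **{f"subgroup_{k}": v for k, v in subgroup_n.items()},
                },
            },
        )
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config {config.config_hash()}): {exc}"
        ) from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_cohort_csv(cohort, outdir / "cohort.csv")
        if cohort.grades is not None:
            io.write_vasculature_csv(cohort, outdir / "vasculature.csv")
        io.write_provenance(analysis, outdir / "provenance.json")
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.md").write_text(render_report(report, "markdown"))
    return report


def _fmt(x, alpha: float, is_p: bool = False) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "na"
    if isinstance(x, float):
        s = f"{x:.3f}"
        if is_p and x < alpha:
            return f"**{s}**"
        return s
    return str(x)


def render_report(report: AnalysisReport, format: str = "markdown") -> str:
    """Render to ``json`` (full precision) or ``markdown`` (3 decimals,
    significant p-values in bold, skipped subgroups as "na" rows)."""
    if format == "json":
        return report.to_json()
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")
    alpha = float(report.provenance.get("alpha", 0.05))
    lines: list[str] = ["# Collateral-score analysis report", ""]
    s = report.summary
    lines += [
        f"Admissions: {s['n_admissions']}; analysis set: {s['n_analysis']} "
        f"(removed: {s['exclusions_removed']})",
        "",
        f"Age {s['age_mean']:.1f} ± {s['age_sd']:.1f}; male {s['male_fraction']:.1%}; "
        f"TIA reclassifications: {s['tia_n']}",
        "",
        "## Inter-outcome correlations",
        "",
    ]
    for k, v in sorted(report.inter_outcome_corr.items()):
        lines.append(f"- {k}: {v:.3f}")
    lines += ["", "## Univariate screen", ""]
    for name, block in report.univariate.items():
        lines.append(f"### {name}")
        lines.append("")
        if "skipped" in block:
            lines += [f"{block['skipped']}", ""]
            continue
        lines.append("| outcome | predictor | kind | effect | p |")
        lines.append("|---|---|---|---|---|")
        for r in block["associations"]:
            lines.append(
                f"| {r['outcome']} | {r['predictor']} | {r['kind']} | "
                f"{_fmt(r['effect_size'], alpha)} | {_fmt(r['p_value'], alpha, True)} |"
            )
        lines.append("")
    lines += ["## Regression models", ""]
    for name, per_outcome in report.regressions.items():
        lines.append(f"### {name}")
        lines.append("")
        for out_name, fit in per_outcome.items():
            if "skipped" in fit:
                lines += [
                    f"**{out_name}**: {fit['skipped']} — F na, p na, adj R² na",
                    "",
                ]
                continue
            lines.append(
                f"**{out_name}** (n={fit['n_used']})"
            )
            lines.append("")
            lines.append("| predictor | t | p | β |")
            lines.append("|---|---|---|---|")
            for pred in fit["predictors"]:
                lines.append(
                    f"| {pred} | {_fmt(fit['t'][pred], alpha)} | "
                    f"{_fmt(fit['p'][pred], alpha, True)} | "
                    f"{_fmt(fit['beta_std'][pred], alpha)} |"
                )
            lines.append(
                f"| overall | F={_fmt(fit['f_value'], alpha)} "
                f"df=({fit['df_model']:.0f}, {fit['df_resid']:.0f}) | "
                f"{_fmt(fit['f_pvalue'], alpha, True)} | "
                f"adj R²={_fmt(fit['adj_r2'], alpha)} |"
            )
            lines.append("")
    lines += ["## MANOVA (Pillai's trace)", ""]
    for name, block in report.manova.items():
        lines.append(f"### {name}")
        lines.append("")
        if "skipped" in block:
            lines += [f"{block['skipped']}", ""]
            continue
        lines.append("| term | Pillai | F | df | p |")
        lines.append("|---|---|---|---|---|")
        for term, st in block["terms"].items():
            lines.append(
                f"| {term} | {_fmt(st['pillai'], alpha)} | {_fmt(st['f_value'], alpha)} | "
                f"({st['df1']:.0f}, {st['df2']:.0f}) | {_fmt(st['p'], alpha, True)} |"
            )
        lines.append("")
    lines += [
        "## Provenance",
        "",
        f"seed {report.provenance['seed']}, config {report.provenance['config_hash']}, "
        f"package {report.provenance['package_version']}",
        "",
    ]
    return "\n".join(lines)
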