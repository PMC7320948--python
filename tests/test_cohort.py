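"""Synthetic cohort generator: determinism, marginals, mechanisms."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from collatscore.cohort import (
    CohortTable,
    EffectBlock,
    GeneratorConfig,
    apply_exclusions,
    generate_admissions,
    generate_vasculature,
    planted_design_for,
)
from collatscore.grading import whole_brain_score
from collatscore.io import write_cohort_csv


def _csv_bytes(cohort) -> bytes:
    buf = _io.StringIO()
    cohort.table.to_csv(buf, index=False)
    return buf.getvalue().encode()


def test_same_config_and_seed_is_byte_identical(default_config):
    a = generate_admissions(default_config, seed=5)
    b = generate_admissions(default_config, seed=5)
    assert _csv_bytes(a) == _csv_bytes(b)
    assert np.array_equal(a.grades, b.grades)


def test_different_seeds_differ(default_config):
    a = generate_admissions(default_config, seed=5)
    b = generate_admissions(default_config, seed=6)
    assert _csv_bytes(a) != _csv_bytes(b)


def test_seed_is_mandatory(default_config):
    with pytest.raises(ValueError, match="seed"):
        generate_admissions(default_config, None)


class TestExclusions:
    def test_default_cohort_yields_530_analysis_records(self, admissions):
        kept = apply_exclusions(admissions)
        assert len(admissions) == 686
        assert len(kept) == 530
        removed = kept.provenance["exclusions_removed"]
        assert removed == {
            "data_quality": 69,
            "alternative_diagnosis": 87,
            "total": 156,
        }

    def test_order_preserved_and_no_flagged_left(self, admissions):
        kept = apply_exclusions(admissions)
        assert (kept.table["excluded"] == "none").all()
        ids = kept.table["patient_id"].tolist()
        original = [
            p
            for p, e in zip(
                admissions.table["patient_id"], admissions.table["excluded"]
            )
            if e == "none"
        ]
        assert ids == original

    def test_no_flags_is_identity(self):
        cfg = GeneratorConfig(
            n_admissions=50,
            n_excluded_data_quality=0,
            n_excluded_alternative_diagnosis=0,
        )
        cohort = generate_admissions(cfg, seed=1)
        kept = apply_exclusions(cohort)
        assert len(kept) == 50
        pd.testing.assert_frame_equal(kept.table, cohort.table)

    def test_excluded_records_carry_no_outcomes(self, admissions):
        excluded = admissions.table[admissions.table["excluded"] != "none"]
        for col in ("fiv_ml", "nihss_discharge", "mrs_discharge"):
            assert excluded[col].isna().all()


class TestMarginalFidelity:
    """Configured prevalences recovered within 3 SE on the analysis set."""

    def test_binary_prevalences(self, analysis_cohort, default_config):
        df = analysis_cohort.table
        n = len(df)
        targets = {
            "male": default_config.male_fraction,
            **{
                k: v
                for k, v in default_config.prevalence.items()
            },
            "tia": default_config.tia_fraction,
        }
        for col, p in targets.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(df[col].mean() - p) <= 3 * se, col

    def test_treatment_mix(self, analysis_cohort, default_config):
        df = analysis_cohort.table
        n = len(df)
        counts = df["treatment"].value_counts(dropna=False)
        for level, p in default_config.treatment_probs.items():
            got = counts.get(level, 0) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(got - p) <= 3 * se, level
        missing = df["treatment"].isna().mean()
        p = default_config.treatment_missing_prob
        assert abs(missing - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_age_distribution(self, analysis_cohort, default_config):
        age = analysis_cohort.table["age"]
        assert age.between(default_config.age_min, default_config.age_max).all()
        # truncation pulls the realized mean slightly below the location 65.7
        assert abs(age.mean() - default_config.age_mean) < 3.0

    def test_fiv_skew(self, analysis_cohort):
        fiv = analysis_cohort.table["fiv_ml"].dropna()
        frac = (fiv < 15).mean()
        se = np.sqrt(0.66 * 0.34 / len(fiv))
        assert abs(frac - 0.66) <= 3 * se

    def test_outcome_ranges(self, analysis_cohort):
        df = analysis_cohort.table
        assert (df["fiv_ml"] >= 0).all()
        assert df["nihss_discharge"].between(0, 42).all()
        assert df["mrs_discharge"].between(0, 6).all()
        assert df["mrs_admission"].between(0, 6).all()


class TestVasculatureGeneration:
    def test_burden_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="burden"):
            generate_vasculature(1.5, rng)

    def test_zero_burden_sheets_are_mostly_normal(self, rng):
        scores, normal_frac = [], []
        for _ in range(50):
            sheet = generate_vasculature(0.0, rng)
            scores.append(whole_brain_score(sheet).whole_brain_score)
            codes = list(sheet.as_dict().values())
            normal_frac.append(np.mean([c == 1 for c in codes]))
        assert np.mean(normal_frac) > 0.85
        assert np.mean(scores) > 40

    def test_mean_score_decreases_with_burden(self, rng):
        means = []
        for b in (0.0, 0.5, 1.0):
            scores = [
                whole_brain_score(generate_vasculature(b, rng)).whole_brain_score
                for _ in range(200)
            ]
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]
        assert means[1] > (means[2] + 5) and means[0] > (means[1] + 5)

    def test_batch_scores_match_reference_scorer(self, admissions):
        for row in range(0, 100, 5):
            sheet = admissions.patient_vasculature(row)
            b = whole_brain_score(sheet)
            rec = admissions.table.iloc[row]
            assert b.whole_brain_score == rec["whole_brain_score"]
            assert b.pial_only_score == rec["pial_only_score"]


def test_null_config_decorrelates_score_and_fiv():
    cfg = GeneratorConfig.null()
    cohort = apply_exclusions(generate_admissions(cfg, seed=8))
    df = cohort.table
    r = np.corrcoef(df["whole_brain_score"], np.log(df["fiv_ml"]))[0, 1]
    assert abs(r) < 3 / np.sqrt(len(df))


def test_planted_design_matches_declared_columns(analysis_cohort, default_config):
    X = planted_design_for(analysis_cohort, default_config)
    assert list(X.columns) == list(default_config.effects.coef_vector("fiv").index)
    missing_tx = analysis_cohort.table["treatment"].isna()
    assert X.loc[missing_tx, "tx_iv"].isna().all()


class TestConfigValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(ValidationError, match="male_fraction"):
            GeneratorConfig(male_fraction=1.2)

    def test_treatment_probs_must_not_exceed_one(self):
        with pytest.raises(ValidationError, match="treatment"):
            GeneratorConfig(
                treatment_probs={
                    "iv_thrombolysis": 0.9,
                    "ia_thrombolysis": 0.2,
                    "thrombectomy": 0.0,
                    "none": 0.0,
                }
            )

    def test_exclusions_cannot_exceed_admissions(self):
        with pytest.raises(ValidationError, match="exclusions"):
            GeneratorConfig(n_admissions=100, n_excluded_data_quality=90,
                            n_excluded_alternative_diagnosis=20)

    def test_effect_keys_must_be_design_columns(self):
        with pytest.raises(ValidationError, match="not in the planted design"):
            EffectBlock(fiv={"not_a_column": 1.0})

    def test_residual_sd_positive(self):
        with pytest.raises(ValidationError, match="> 0"):
            EffectBlock(fiv_resid_sd=0.0)


def test_cohort_table_rejects_duplicate_ids(analysis_cohort):
    df = analysis_cohort.table.copy()
    df.loc[1, "patient_id"] = df.loc[0, "patient_id"]
    with pytest.raises(ValueError, match="duplicate patient_id"):
        CohortTable(df)


def test_cohort_csv_write_is_deterministic(tmp_path, default_config):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_csv(generate_admissions(default_config, seed=3), p1)
    write_cohort_csv(generate_admissions(default_config, seed=3), p2)
    assert p1.read_bytes() == p2.read_bytes()
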