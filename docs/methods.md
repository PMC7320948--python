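# Methods

## Scoring model

The grading sheet covers 34 slots: 11 paired graded vessels (VA, Pcom, ICA
and the A1–A2, M1–M3, P1–P3 segments; codes −4…1), two unpaired midline
vessels (BAS, Acom; single grade each, not doubled), and 5 paired
accessory vessels scored only for assessability (0/1). Two pial artery
counts (cortical, cerebellar) are thresholded to 0–2 scores.

Aggregation: left + right per vessel; proximal weighting ACA = 2·A1 + A2,
MCA = 4·M1 + 2·M2 + M3, PCA = 4·P1 + 2·P2 + P3; the internal carotid enters
as a single side-summed factor without intra-ICA weighting; all components,
assessability points and pial scores are summed without further weights.
The additive combination is the simplest rule consistent with the scheme's
per-vessel construction; the breakdown object exposes every summand so the
whole-brain value is auditable (it equals the component sum exactly, by
construction and by test).

Conventions for edge codes:

- "not assessable" (0) contributes 0 — neutral, not missing. The sheet has
  no missing-data rule; treating 0 as missing would make the score
  undefined for nearly every real sheet.
- A cerebellar pial count of 0 means "not visible / not assessable" and
  scores 0; counts are whole-brain, not per hemisphere.
- Codes outside a vessel's allowed set are rejected with the vessel and
  side named; incomplete or duplicated sheets are rejected listing slots.

Range: the score lies in [−168, 56]; 56 is attained by the all-normal
sheet, −168 by bilateral occlusion of every graded vessel with nothing
assessable and no pial collaterals. Because all aggregation weights are
positive, improving any single grade can never lower the score
(tested by exhaustive single-slot perturbation).

## Synthetic cohort generator

The generator emulates a consecutive emergency-department stroke cohort so
the analysis stack can be developed and power-checked without patient
data. The default configuration encodes the emulated study design: 686
admissions, 69 + 87 exclusion flags (analysis set 530), age 65.7 ± 15.0
truncated to [19, 90], 60.9% male, prevalences (atherosclerosis 0.33,
smoking 0.391, elevated glucose 0.053, infection 0.025, statin 0.25 — the
statin prevalence is not reported anywhere and was set to a typical
secondary-prevention rate), treatment mix 0.322/0.06/0.02/0.551 with the
4.7% remainder carried as a missing treatment record, 17.2% TIA
reclassifications, 16.4% unknown symptom onset, and a territory mix with
64% MCA (back-derived from the reported LVOS share of the MCA subgroup).

Generative chain:

1. **Latent burden.** A logistic function of atherosclerosis, smoking,
   glucose, standardized age and noise gives an atherosclerotic-burden
   value in (0, 1).
2. **Vasculature.** Each graded slot draws from a per-slot categorical
   distribution linearly interpolated between a near-normal profile and a
   heavily diseased profile by burden; assessability probabilities and
   pial Poisson rates decline in burden. Expected score is therefore
   strictly decreasing in burden (Monte-Carlo tested).
3. **Score.** Sheets are scored by the same aggregation as the public
   scorer (batch path tested against it row by row).
4. **Treatment and TIA.** Assignment uses a severity-ordered propensity
   (worse collaterals → more intervention; better collaterals → more
   likely TIA reclassification) normalised so the configured marginals are
   preserved; strengths are configurable and zero in the null config.
5. **Outcomes.** log FIV is a *linear model on the planted design*
   (standardized score, centred pial score, risk factors, standardized
   age, sex, treatment dummies) plus a shared latent u and independent
   noise; FIV = exp(·) keeps volumes positive so OLS on log FIV recovers
   the planted coefficients without censoring bias. NIHSS and mRS arise by
   monotone binning of a shared latent severity (its own linear model plus
   the same u), which induces inter-outcome correlations of realistic
   magnitude (~0.5–0.65) without fitting them exactly. TIA records
   override the discharge outcomes with a near-zero FIV mass and mild
   NIHSS/mRS — they sit outside the linear FIV model, so recovery analyses
   condition on non-TIA records.

Default planted effects (log-ml per unit): score −1.40 per reference SD,
pial −0.15/point, atherosclerosis +0.25, glucose +0.35, age +0.10 per SD,
IV/IA/thrombectomy offsets +0.30/+1.20/+0.90; severity loadings −0.55,
+0.30, +0.45, +0.25 on score/atherosclerosis/glucose/age. Reference
standardisation constants (score 16 ± 20), the FIV intercept 1.539 and the
mRS bin edges were frozen from a single 50,000-record calibration run
targeting the reported cohort marginals: 66% of FIV below 15 ml, FIV median
near 2 ml, NIHSS medians 6 (admission) / 1 (discharge), mRS medians 3 / 2.
The emulated cohort's reported summaries give two mutually inconsistent
central FIV values (2.76 and 1.94 ml); calibration targets the smaller one
but the 66% < 15 ml constraint takes precedence, landing the median at
≈ 2–4 ml and the > 100 ml tail at ≈ 18% (reported: 13.3%).

`GeneratorConfig.null()` removes *every* predictor–outcome dependence —
planted effects, the severity pull on treatment, and the collateral pull on
TIA — making it the reference condition for type-I-error studies.

All randomness flows from a single `numpy` generator seeded explicitly;
the seed is mandatory and identical (config, seed) pairs are byte-identical.

What the generator does **not** emulate: within-patient spatial structure
of disease (grades are conditionally independent given burden), measurement
error in FIV, time-to-treatment dynamics, correlated missingness, or the
real cohort's joint distribution beyond the configured marginals and
planted effects. Passing tests therefore demonstrate correctness of the
machinery and calibration under these assumptions, not fidelity to any
real population.

## Statistical stage

- **Screen.** Pearson's r with the exact t on n−2 df for continuous
  predictors; Pearson χ² (no continuity correction) with Cramér's V for
  categorical ones, using quartile bins of the outcome (ties merge bins;
  empty bins are compressed). Raw p-values, pairwise deletion. Written
  descriptions of the emulated analysis pair the tests the other way
  around; the implemented routing is the standard one and matches which
  effect size that analysis reports per predictor type. The
  pipeline screens log1p(FIV) rather than raw ml: on volumes this skewed, a
  raw-scale Pearson r is numerically meaningless (≈ −0.06 for a strongly
  planted effect).
- **Regression.** OLS via statsmodels; listwise deletion per model; SEs
  from the unbiased residual variance; standardized β by z-scoring the
  outcome and every predictor including binaries (the convention of the
  major commercial packages); adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).
  Rank-deficient designs are rejected naming the implicated columns.
  NIHSS and mRS are modelled as continuous despite their ordinal scale —
  reproducing the analysis style being emulated; an ordinal model would be
  the methodologically stricter choice and is deliberately out of scope.
  FIV enters as log1p(FIV) by default (raw optional).
- **MANOVA.** Pillai's trace per predictor (1-df contrasts) plus a joint
  all-slopes "omnibus" term, with the standard F approximation. The
  statistic is computed from the hypothesis/error cross-product matrices
  directly; it agrees with statsmodels' MANOVA to machine precision and
  reduces exactly to the OLS overall F for a single outcome. Pillai was
  chosen as the most robust of the classical MANOVA statistics and the
  default of the emulated tooling; others are not implemented.
- **Subgroups.** Territory filters, FIV bands (15–100 ml, > 100 ml) and an
  NIHSS > 17 threshold, combinable as intersection or union (the malignant
  profile is the union). A subgroup below the minimum n (default 20,
  ≥ predictors + 2) is reported "not analyzable (n too small)", never
  fitted.

## Pipeline

`run_pipeline` executes simulate (or load) → exclusions → screen →
regressions → MANOVA → report. Every configured subgroup appears exactly
once in the report, with fits or a skip reason; per-stage n is logged and
recorded in provenance together with the seed and a config hash. Report
JSON is fully deterministic (sorted keys, full precision); the markdown
rendering rounds to 3 decimals and bolds p < α (default 0.05), with "na"
entries for skipped blocks.

## Problem sizes used in the tests

The acceptance-style tests run at the cohort's own scale (n = 686 → 530):
1000 replicates for screen calibration and coefficient-recovery coverage,
500 for the null adjusted-R² mean, 200 Monte-Carlo draws for generator
monotonicity, 100 random sheets for exhaustive perturbation, and 1000
random small problems per statistic oracle. Coverage of a correctly
specified OLS coefficient at ±2 estimated SE is exactly 2·T_df(2) − 1
≈ 0.954; the recovery check uses 1000 replicates so that its per-cell
binomial noise (≈ 0.7 pp) is small relative to the 93% pass line.

## Known limitations

- Ordinal outcomes treated as continuous (above).
- The χ² path can meet sparse cells for rare binaries (infection, 2.5%)
  against quartile bins; expected counts ≈ 3 keep the test near nominal at
  n = 530 but it would degrade in much smaller cohorts.
- Regional/lesion-side-relative scoring and image-derived grading are out
  of scope by design; grades are inputs.
- The generator's planted effects are on the score, not on individual
  vessels, so vessel-level inference questions cannot be studied with it.
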