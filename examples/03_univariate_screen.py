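"""Univariate association screen against the discharge outcomes.

Each continuous predictor (age, collateral scores, baseline NIHSS) is
correlated with each outcome via Pearson's r; each categorical predictor
(risk factors, sex, treatment) is tested with a chi-square on predictor
level x outcome quartile and summarised as Cramér's V.  Expect a clearly
negative score-FIV correlation (better collaterals -> smaller infarcts) and
near-zero effects for predictors the generator leaves unlinked (statin).
"""

import numpy as np

from collatscore import GeneratorConfig, apply_exclusions, generate_admissions, univariate_screen
from collatscore.pipeline import DEFAULT_UNIVARIATE_PREDICTORS

cohort = apply_exclusions(generate_admissions(GeneratorConfig(), seed=1))
df = cohort.table.assign(log1p_fiv=np.log1p(cohort.table.fiv_ml))

results = univariate_screen(
    df, ["log1p_fiv", "nihss_discharge", "mrs_discharge"], DEFAULT_UNIVARIATE_PREDICTORS
)

print(f"{'outcome':<16} {'predictor':<20} {'kind':<10} {'effect':>8} {'p':>10}")
for r in results:
    flag = " *" if r.p_value < 0.05 else ""
    print(
        f"{r.outcome:<16} {r.predictor:<20} {r.kind:<10} "
        f"{r.effect_size:>8.3f} {r.p_value:>10.4f}{flag}"
    )
print("\n* p < 0.05 (raw two-sided p-values, no multiplicity adjustment)")
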