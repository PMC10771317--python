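"""Prognostic value of tumor-vs-normal numTS changes.

Builds a paired cohort with planted delta-numTS hazards, fits the three
Cox models (clinical-only, numts-clinical via unpenalized-clinical
LASSO-Cox selection, expr-clinical on the same families' expression
changes), stratifies patients at the median predicted hazard, and
compares the models with likelihood-ratio tests.
"""

import warnings

warnings.filterwarnings("ignore")

from numts import core, survival
from numts.simulate import SimConfig, simulate_paired_cohort, simulate_survival

cfg = SimConfig(seed=3, n_pairs=120, n_families=30)
cohort = simulate_survival(cfg, simulate_paired_cohort(cfg))

delta_numts = cohort.truth["delta_numts"]
clin = (cohort.clinical[cohort.clinical.tissue == "tumor"]
        .drop_duplicates("patient_id").set_index("patient_id")
        .loc[delta_numts.columns])
design = survival.encode_clinical(clin)
delta_expr = core.delta_numts(cohort.mirna_expr, cohort.clinical)

models = survival.build_survival_model_set(
    design, delta_numts, delta_expr[delta_numts.columns],
    clin["surv_time"], clin["event"], seed=0)

print(f"planted hazard families: {cohort.truth['planted_hazard_features']}")
print(f"LASSO-Cox selected:      {models.selected_families}")
print(f"LRT numts-clinical vs clinical-only: "
      f"stat={models.lrt_numts.statistic:.1f}, p={models.lrt_numts.p:.2e}")
print(f"LRT expr-clinical  vs clinical-only: "
      f"stat={models.lrt_expr.statistic:.1f}, p={models.lrt_expr.p:.2e}")
for name, strat in models.risk.items():
    if strat is not None:
        print(f"log-rank p ({name}): {strat.logrank_p:.3g}")
print("\nA large numts-clinical LRT with a null expr-clinical LRT shows the")
print("prognostic signal lives in the target-site change, not in the")
print("expression change of the same miRNA families.")
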