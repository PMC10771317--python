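# numts

Quantification of **miRNA target-site abundance under alternative
polyadenylation (APA)**, and the downstream analyses that turn it into a
cancer biomarker.

## The problem

miRNAs repress mRNAs by binding target sites that sit mostly in 3'UTRs.
Tumors remodel 3'UTRs through APA: switching from the distal to the
proximal polyA site removes the distal UTR segment and every target site
on it.  The abundance of a miRNA therefore tells only half the story of
its binding activity — the other half is how many **binding
opportunities** exist in the transcriptome, which APA changes
sample-by-sample.  This package computes that quantity, the **number of
miRNA target sites (numTS)**, and provides the statistical machinery to
use it as a biomarker for tumor phenotypes, immunotherapy response and
survival.

For a gene *x* whose 3'UTR is split by the proximal polyA boundary into a
constitutive segment (pUTR, on every isoform) and a distal segment
(dUTR, only on the long isoform), with PDUI(*x*) ∈ [0, 1] the fraction of
transcripts carrying the long isoform:

```
numTS(x, j) = ( pUTR(x, j) + dUTR(x, j) · PDUI(x) ) · FPKM(x)
numTS(j)    = Σ_x numTS(x, j)          (over all expressed genes)
```

where pUTR(*x*, *j*) and dUTR(*x*, *j*) count the family-*j* target sites
in the two segments.  The result is a miRNA-family × sample matrix,
computable from RNA-Seq alone (no miRNA sequencing needed).

On top of the matrix the package implements:

* **association** — per-family squared Spearman correlation between
  numTS and miRNA expression, the Wilcoxon rank-sum test for its
  disruption in tumors, and the BH-significant correlated set;
* **separation** — log2/center/scale preprocessing, hierarchical
  clustering, PCA, between-group variance rate, pairwise Mahalanobis
  distances between sample groups;
* **regression** — elastic-net prediction of phenotype scores with
  nested cross-validation (75/25 outer splits, inner 10-fold, one-SE
  rule), paired feature-set comparison, bootstrap stability selection
  (selection frequency over 200 resamples), exact hypergeometric overlap
  tests;
* **survival** — Cox models with LASSO-selected ΔnumTS features
  (clinical covariates unpenalized), median-split risk groups,
  Kaplan–Meier/log-rank, likelihood-ratio model comparison;
* **simulate** — a synthetic-cohort generator with the full generative
  structure (Beta PDUI with tumor shortening, log-normal expression,
  copula-coupled miRNA expression, planted outcome and hazard features),
  so every analysis is testable end to end without external data.

## Worked example

```python
from numts import association
from numts.simulate import SimConfig, simulate_paired_cohort

cohort = simulate_paired_cohort(SimConfig(seed=1, n_pairs=40, n_families=100))
cols = cohort.numts.columns
normal = [s for s in cols if s.endswith("_N")]
tumor  = [s for s in cols if s.endswith("_T")]

prof_n = association.correlation_profile(cohort.numts[normal], cohort.mirna_expr[normal])
prof_t = association.correlation_profile(cohort.numts[tumor],  cohort.mirna_expr[tumor])
print(association.disruption_test(prof_t, prof_n))
```

prints (`examples/02_coupling_disruption.py` runs the full version):

```
median rho^2 normal: 0.643
median rho^2 tumor:  0.016
rank-sum p = 2.56e-34 (normal > tumor)
100.0% of families have no significant tumor coupling
```

The normal-tissue coupling between a family's expression and its binding
opportunities (median ρ² = 0.64) collapses in tumor samples (0.02); the
rank-sum test on the ρ² distributions detects the disruption at
p ≈ 10⁻³⁴.  The other scripts in `examples/` demonstrate the numTS
computation itself, the predictive comparison against miRNA expression
(61% RMSE decrease when the outcome is target-site-driven), stability
selection, the survival model trio and the ICB four-group separation.

A command-line interface mirrors the library:

```bash
numts simulate --kind paired --seed 1 --out cohort/
numts compute --expr cohort/expr.tsv --apa cohort/apa.tsv \
              --sites cohort/sites.tsv --out numts.tsv
numts correlate --numts numts.tsv --mirna cohort/mirna.tsv --out profile.tsv
```

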