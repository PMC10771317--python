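# Methods

## The numTS model

A gene's 3'UTR is modeled as two segments split at the proximal polyA
boundary: the constitutive proximal segment (pUTR), present on every
isoform, and the distal segment (dUTR), present only on the long
isoform.  With PDUI the fraction of the gene's transcripts using the
distal polyA site, the expected number of family-*j* sites carried by
gene *x* in a sample is `(pUTR(x,j) + dUTR(x,j)·PDUI(x)) · FPKM(x)`, and
numTS(*j*) sums this over all expressed genes.  FPKM enters untransformed:
the quantity is a site *census* scaled by transcript abundance, so it is
linear (homogeneous of degree 1) in expression and monotone in PDUI.
Log transforms appear only in downstream analysis preprocessing.

Site partitioning: a site belongs to pUTR only when its interval ends at
or before the boundary.  A site straddling the boundary is truncated by
proximal polyadenylation — only the long isoform carries an intact copy —
so it is counted as distal.  Genes with no APA call are treated as
PDUI ≡ 1 with all sites constitutive (no detected APA means the
full-length UTR; the two encodings give the same value).  A missing PDUI
for a (gene, sample) drops that gene from that sample's sum by default
(`missing_pdui="skip"`); cohort-mean imputation is available behind
`missing_pdui="mean"` but is never the default, to avoid silent
imputation.

Coordinates are transcript-local, 0-based, half-open; readers convert
1-based inclusive genomic input and flip minus-strand loci so position 0
is the 5' end of the UTR in transcript orientation.  Downstream code is
therefore strand-free.

ΔnumTS (tumor minus normal, per patient) is computed on the log2(x+1)
scale by default so hazard coefficients are comparable across families
whose absolute site abundances differ by orders of magnitude; raw
differences are available via `transform="raw"`.

## Association analyses

Per family, Spearman's ρ between the numTS row and the expression row
over samples; the reported quantity is ρ².  p-values use the
t-approximation for n > 8 and exact permutation enumeration for n ≤ 8;
families with a constant vector are flagged missing and excluded from
the Benjamini–Hochberg correction (q < 0.05 defines the correlated set).
The tumor-vs-normal disruption test is a two-sided Wilcoxon rank-sum on
the two ρ² distributions, treated as unpaired; a paired signed-rank
variant is exposed behind `paired=True` for users who want to exploit
the family pairing.

## Separability metrics

Preprocessing for clustering/PCA/rate is log2(x+1), then per-feature
centering and unit-variance scaling (population SD); constant features
are dropped with a warning.  Hierarchical clustering uses Euclidean
distance with complete linkage by default (average/ward selectable) —
deterministic given input order.  The between-group rate is the pooled
one-way ANOVA decomposition after per-feature unit scaling:
`100 · Σ_f SS_between(f) / Σ_f SS_total(f)`; the ratio-of-sums
aggregation makes it a single well-defined estimand that is invariant to
per-feature affine rescaling.  Mahalanobis distances between group
centroids use the pooled within-group covariance of each pair (not the
global covariance): pairwise separability relative to the pair's own
spread is the quantity a pair of confidence ellipses illustrates.
Ellipse drawing itself is a plotting concern and not part of the
computational contract.

## Elastic-net machinery

Penalty paths are computed per mixing parameter (l1 ratio) as 20
geometric steps from the smallest penalty that zeroes every coefficient
down to 10⁻³ of it, and cross-validated with k-fold CV; the one-SE rule
then picks the largest penalty whose mean CV error is within one
standard error of the minimum, with ties broken toward the larger l1
ratio.  Mixing parameters run over the 11-point grid {0.0, 0.1, …, 1.0};
a ratio of 0 is floored at 0.01 inside the coordinate-descent solver,
where a pure ridge path is unreliable.  Feature standardization is
always computed on the training portion of the split at hand — outer
training sets, inner CV folds, bootstrap resamples — never on held-out
samples.

Nested CV draws repeated random 75/25 train/test splits (the default 300
repeats mirrors the intended production setting; tests and the
acceptance script use 10–50 repeats to stay desk-scale), tunes on the
training part, and records held-out RMSE.  Feature-set comparisons share
the outer splits (identical seed-derived permutations), so the RMSE
difference is a paired contrast; the summary is the percent decrease of
mean RMSE.

Bootstrap stability selection resamples samples with replacement,
refits an elastic net per resample with the penalty tuned by inner
10-fold CV (one-SE rule), and reports each feature's selection
frequency.  Two deliberate choices here:

* **Fold assignment by sample identity.**  A bootstrap sample contains
  duplicates; if duplicates of one observation land on both sides of an
  inner CV split, the CV error rewards memorization and noise features
  are selected persistently.  Folds are therefore formed over the unique
  original indices, which restores the null behavior (no feature exceeds
  the 70% frequency cutoff under a pure-noise outcome).
* **Fixed mixing parameter (0.5) with a shortened 15-step path** in the
  bootstrap loop: cross-validating only the penalty strength per
  resample is the standard workflow for selection (the grid search over
  mixing parameters adds ~30× cost without changing which features are
  stable).

The predictive set is either the top half of features ranked by
frequency (ties at the cutoff included, never-selected features
excluded) or the features above a 70% frequency cutoff.  Replication
between two cohorts is scored with the exact upper-tail hypergeometric
probability of the observed overlap given an explicit feature universe.

## Survival models

Three Cox models per cohort: clinical-only; numts-clinical, whose extra
covariates are the ΔnumTS features selected by a LASSO-Cox in which
clinical covariates carry penalty factor 0 (always kept) and family
features penalty factor 1; and expr-clinical, which adds the
Δexpression of exactly the numTS-selected families (same log2(x+1)
difference transform).  The LASSO penalty strength is chosen by 10-fold
cross-validated concordance on held-out folds under a one-SE-style rule
(largest penalty within one SE of the best mean concordance).  Because a
likelihood-ratio test on penalized fits is not well defined, both
augmented models are refit unpenalized on the selected covariates before
likelihood comparison; the resulting inference is descriptive, not
selective-inference-corrected.  Ties in event times use the Efron
approximation.  Risk stratification splits at the median linear
predictor via ranks (top half = high risk), making group sizes differ by
at most one and the split invariant to monotone transforms of the
predictor; groups are compared with the two-sided log-rank test.
Clinical covariates are coded age-continuous, gender-binary and
stage-ordinal by default, with dummy coding for stage behind a flag.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume:

* **Sites** — per (gene, family) counts are Poisson(0.3) over 300 genes
  × 100 families, giving ≈ 90 sites per family; each site falls in pUTR
  or dUTR with equal probability, as an explicit interval in a 2 kb UTR.
* **PDUI** — Beta-distributed around a per-gene mean drawn from
  U(0.55, 0.9) with concentration 10; the tumor mean is shifted down by
  0.2 (3'UTR shortening).
* **Expression** — log-normal FPKM (gene-level mean N(2, 1) on the
  natural-log scale, sample noise SD 0.7) and TPM.
* **Coupling** — miRNA-family expression is tied to the true numTS row
  through a Gaussian copula on ranks, using the exact relation
  r = 2·sin(πρ/6) between the latent Pearson correlation and the target
  Spearman ρ: 0.8 in normal tissue, 0.0 in tumors.
* **Outcomes** — y = Σ β·z(numTS) over 5 planted families (β = 1) plus
  N(0, 1) noise; a mirror outcome driven by the same families'
  *expression* supports the sign-flip control.
* **Survival** — Weibull-baseline (shape 1.5, scale 365 days)
  proportional hazards with log-HR 0.7 per standardized planted ΔnumTS
  feature and 0.3 per standardized age; censoring is uniform with its
  upper bound tuned by bisection to a 30% target rate.
* **ICB layout** — four equal groups (responder/non-responder ×
  pre/post, 25 samples each); a mean shift of 2 within-group SDs is
  planted on the planted families' numTS in responder-post samples only.
  The shift is applied to the returned feature matrix directly (PDUI is
  gene-level and shared across families, so a clean per-family shift is
  not expressible upstream); the unshifted tables and matrix are kept in
  the ground-truth record, whose numTS always equals the core
  computation on the generated tables to 10⁻⁹.

Everything is deterministic given the seed.  What the simulator does
*not* emulate: realistic cohort-scale marginal distributions beyond these
distributional families, read-level noise, gene–gene co-expression
structure, batch effects, or dependence between PDUI and expression.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the stated generative model, not performance
on real cohorts.

## Numerical choices and degenerate inputs

* Coordinate-descent path fits use tolerance 10⁻³; agreement of the
  vectorized numTS computation with the per-site oracle is asserted at
  10⁻⁹.
* A constant outcome yields the intercept-only model (RMSE 0), not an
  error; constant features receive coefficient 0.
* Degenerate bootstrap resamples (constant outcome) are skipped and
  logged; more than 10% skipped is an error.
* CV folds with no comparable survival pairs score concordance 0.5.
* PCA signs are fixed by making each component's largest-magnitude
  loading positive, for reproducibility.
* Matrix round-trips are bit-exact (round-trip float parsing).

## Problem sizes

Tests and the acceptance script run at the generator defaults (300
genes, 100 families, 200 tumor samples or 40–150 tumor/normal pairs)
with 10–50 nested-CV repeats and 100–200 bootstraps — sizes chosen so
stability selection and the survival pipeline are well-posed while a
full run stays in the minutes range on a laptop.

## Known limitations

Post-selection inference in the survival trio is descriptive; the
hypergeometric universe must be supplied explicitly (what counts as
"tested in both cohorts" is a design decision); the rank-based copula
controls Spearman correlation exactly only asymptotically; and the
predictive layer is elastic-net only — non-linear learners (random
forests, kernel SVMs) are outside the package's scope.
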