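"""Compute the numTS matrix for a small synthetic cohort.

Builds a cohort (gene FPKM, 3'UTR loci with PDUI, target-site intervals),
partitions the sites at the proximal polyA boundary, and aggregates the
PDUI-weighted, FPKM-scaled site counts into a miRNA-family x sample
matrix.  Each entry is the expected number of binding opportunities that
family has in that sample's transcriptome.
"""

from numts import core
from numts.simulate import SimConfig, simulate_cohort

cohort = simulate_cohort(SimConfig(seed=0, n_genes=100, n_families=10,
                                   n_samples=6))
counts = core.partition_sites(cohort.sites, cohort.apa)
numts = core.compute_numts_matrix(cohort.expr, cohort.apa, counts)

print("site counts per (gene, family), first rows:")
print(counts.head(3).to_string(index=False))
print("\nnumTS matrix (families x samples):")
print(numts.round(0).iloc[:5, :4])
print("\nA value of e.g. 2000 means that, summed over all expressed genes,")
print("roughly 2000 FPKM-weighted target sites for that family are present")
print("on the isoforms transcribed in that sample.")
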