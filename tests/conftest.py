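import warnings

import numpy as np
import pandas as pd
import pytest

from numts.io import ApaTable
from numts.simulate import SimConfig, simulate_cohort, simulate_paired_cohort

warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")
warnings.filterwarnings("ignore", category=RuntimeWarning, module="lifelines")


def random_instance(seed, n_genes=30, n_families=5, n_samples=8,
                    frac_no_apa=0.2, frac_missing_pdui=0.1):
    """Small random (expr, apa, sites) triple for oracle comparisons.

    Includes genes absent from the APA table and missing PDUI entries, so
    both handling rules are exercised.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:02d}" for i in range(n_samples)]
    families = [f"fam{i}" for i in range(n_families)]
    L = 500
    apa_genes = [g for g in genes if rng.random() > frac_no_apa]
    boundary = rng.integers(100, 400, len(apa_genes))
    loci = pd.DataFrame(
        {"chrom": "chr1",
         "start": np.arange(len(apa_genes)) * 1000,
         "end": np.arange(len(apa_genes)) * 1000 + L,
         "strand": "+",
         "boundary": boundary,
         "utr_length": L},
        index=pd.Index(apa_genes, name="gene_id"),
    )
    pdui = rng.uniform(0, 1, (len(apa_genes), n_samples))
    pdui[rng.random(pdui.shape) < frac_missing_pdui] = np.nan
    apa = ApaTable(loci, pd.DataFrame(pdui, index=loci.index, columns=samples))

    n_sites = n_genes * 3
    rows = []
    for _ in range(n_sites):
        g = genes[rng.integers(n_genes)]
        s = int(rng.integers(0, L - 7))
        rows.append((g, families[rng.integers(n_families)], s, s + 7))
    sites = pd.DataFrame(rows, columns=["gene_id", "mirna_family",
                                        "site_start", "site_end"])
    expr = pd.DataFrame(rng.uniform(0, 50, (n_genes, n_samples)),
                        index=pd.Index(genes, name="gene_id"), columns=samples)
    return expr, apa, sites


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimConfig(seed=11, n_genes=80, n_families=20,
                                     n_samples=40))


@pytest.fixture(scope="session")
def small_paired_cohort():
    return simulate_paired_cohort(SimConfig(seed=12, n_genes=80,
                                            n_families=20, n_pairs=15))
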