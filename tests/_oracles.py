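"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized implementation paths: they loop
over individual sites, samples and p-values so that agreement with the
package is a meaningful cross-check.
"""

import numpy as np
import pandas as pd


def numts_bruteforce(expr, apa, sites, missing_pdui="skip"):
    """Per-site accumulation of (pUTR ? 1 : PDUI) * FPKM.

    Iterates every individual site and sample.  Genes absent from the APA
    table count as fully constitutive; missing PDUI either drops the gene
    for that sample or uses the gene's across-sample mean.
    """
    families = sorted(sites["mirna_family"].unique())
    samples = list(expr.columns)
    out = pd.DataFrame(0.0, index=pd.Index(families, name="mirna_family"),
                       columns=samples)
    row_means = apa.pdui.mean(axis=1, skipna=True)
    for _, site in sites.iterrows():
        g, fam = site["gene_id"], site["mirna_family"]
        if g not in expr.index:
            continue
        in_apa = g in apa.loci.index
        b = apa.loci.loc[g, "boundary"] if in_apa else np.inf
        is_putr = site["site_end"] <= b
        for s in samples:
            fpkm = expr.loc[g, s]
            if not in_apa:
                w = 1.0
            else:
                pdui = apa.pdui.loc[g, s]
                if np.isnan(pdui):
                    if missing_pdui == "skip":
                        continue
                    pdui = row_means.loc[g]
                    if np.isnan(pdui):
                        continue
                w = 1.0 if is_putr else pdui
            out.loc[fam, s] += w * fpkm
    return out


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def spearman_rank_oracle(x, y):
    """Spearman rho by explicit rank substitution then Pearson."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx**2).sum() * (ry**2).sum()))
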