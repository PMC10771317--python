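"""Per-sample, per-miRNA-family target-site abundance (numTS).

A gene's 3'UTR is split by the proximal polyA boundary into a constitutive
proximal segment (pUTR, present on every isoform) and a distal segment
(dUTR, present only on the long isoform).  With PDUI the fraction of
transcripts carrying the long 3'UTR, the expected number of family-j sites
carried by gene x in a sample is

    (pUTR(x, j) + dUTR(x, j) * PDUI(x)) * FPKM(x)

and numTS(j) sums this over all expressed genes.  The result is a
family x sample matrix: an expression-scaled, APA-aware census of how many
binding opportunities each miRNA family has in the transcriptome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ApaTable, ValidationError

__all__ = [
    "partition_sites",
    "gene_family_site_abundance",
    "compute_numts_matrix",
    "delta_numts",
]


def partition_sites(sites: pd.DataFrame, apa: ApaTable) -> pd.DataFrame:
    """Assign each target site to pUTR or dUTR and count per (gene, family).

    Sites are transcript-local, 0-based half-open intervals.  A site is
    constitutive (pUTR) only when it ends at or before the proximal
    boundary; a site straddling the boundary is truncated by proximal
    polyadenylation, so only the long isoform carries an intact copy and
    the site counts as distal.

    Genes absent from the APA table are treated as having no detected APA:
    the full-length 3'UTR is constitutive and all their sites count as pUTR.

    Returns a DataFrame with columns ``gene_id, mirna_family, putr_count,
    dutr_count`` (one row per observed pair).
    """
    required = {"gene_id", "mirna_family", "site_start", "site_end"}
    if not required <= set(sites.columns):
        if {"putr_count", "dutr_count"} <= set(sites.columns):
            return sites  # already counts
        raise ValueError("partition_sites expects per-site intervals")

    boundary = apa.loci["boundary"]
    length = apa.loci["utr_length"]
    rows = sites["gene_id"].to_numpy()
    start = sites["site_start"].to_numpy()
    end = sites["site_end"].to_numpy()

    in_apa = pd.Index(rows).isin(boundary.index)
    b = np.full(len(sites), np.inf)
    b[in_apa] = boundary.reindex(rows[in_apa]).to_numpy()
    L = np.full(len(sites), np.inf)
    L[in_apa] = length.reindex(rows[in_apa]).to_numpy()

    if (start < 0).any() or (end > L).any():
        i = int(np.argwhere((start < 0) | (end > L))[0][0])
        raise ValidationError(
            f"site outside 3'UTR locus for gene {rows[i]!r} "
            f"([{start[i]}, {end[i]}) vs length {L[i]})"
        )

    is_putr = end <= b
    out = pd.DataFrame(
        {
            "gene_id": rows,
            "mirna_family": sites["mirna_family"].to_numpy(),
            "putr_count": is_putr.astype(int),
            "dutr_count": (~is_putr).astype(int),
        }
    )
    counts = (
        out.groupby(["gene_id", "mirna_family"], sort=True, as_index=False)[
            ["putr_count", "dutr_count"]
        ].sum()
    )
    return counts


def gene_family_site_abundance(putr: int, dutr: int, pdui: float, fpkm: float) -> float:
    """Expected site count for one (gene, family, sample): (p + d*PDUI)*FPKM."""
    if not 0.0 <= pdui <= 1.0:
        raise ValueError(f"PDUI must lie in [0, 1], got {pdui}")
    if fpkm < 0:
        raise ValueError(f"FPKM must be non-negative, got {fpkm}")
    return float((putr + dutr * pdui) * fpkm)


def compute_numts_matrix(
    expr: pd.DataFrame,
    apa: ApaTable,
    counts: pd.DataFrame,
    missing_pdui: str = "skip",
) -> pd.DataFrame:
    """Aggregate per-gene site abundance into a family x sample numTS matrix.

    Parameters
    ----------
    expr : gene x sample FPKM matrix (samples must match ``apa.samples``).
    apa : ApaTable with per-sample PDUI; genes in ``expr`` but not in the
        table contribute with PDUI = 1 (no detected APA, full-length UTR).
    counts : output of :func:`partition_sites` (or a precomputed count table).
    missing_pdui : {"skip", "mean"}
        ``skip`` drops a gene from the sample where its PDUI is missing
        (contributes 0); ``mean`` imputes the gene's across-sample mean.

    Entries are non-negative, and exactly 0 when every contributing gene
    has zero FPKM in that sample.
    """
    if missing_pdui not in ("skip", "mean"):
        raise ValueError(f"missing_pdui must be 'skip' or 'mean', got {missing_pdui!r}")
    genes = expr.index.intersection(pd.Index(counts["gene_id"]).unique())
    if len(genes) == 0:
        raise ValidationError("no overlap between expression genes and site counts")
    samples = expr.columns

    families = pd.Index(sorted(counts["mirna_family"].unique()), name="mirna_family")
    gpos = pd.Series(np.arange(len(genes)), index=genes)
    fpos = pd.Series(np.arange(len(families)), index=families)

    sub = counts[counts["gene_id"].isin(genes)]
    P = np.zeros((len(genes), len(families)))  # pUTR counts
    D = np.zeros_like(P)                        # dUTR counts
    gi = gpos[sub["gene_id"]].to_numpy()
    fi = fpos[sub["mirna_family"]].to_numpy()
    np.add.at(P, (gi, fi), sub["putr_count"].to_numpy(dtype=float))
    np.add.at(D, (gi, fi), sub["dutr_count"].to_numpy(dtype=float))

    F = expr.loc[genes, samples].to_numpy(dtype=float)

    pdui = apa.pdui.reindex(index=genes, columns=samples).to_numpy(dtype=float)
    no_apa = ~pd.Index(genes).isin(apa.genes)
    pdui[no_apa, :] = 1.0  # no detected APA -> full-length UTR everywhere
    missing = np.isnan(pdui)
    if missing_pdui == "mean":
        row_mean = np.nanmean(np.where(missing, np.nan, pdui), axis=1)
        still_all_missing = np.isnan(row_mean)
        row_mean[still_all_missing] = 0.0
        pdui = np.where(missing, row_mean[:, None], pdui)
        usable = ~(missing & still_all_missing[:, None])
    else:
        pdui = np.where(missing, 0.0, pdui)
        usable = ~missing

    Fu = F * usable
    # numTS[j, s] = sum_x (P[x,j] + D[x,j]*pdui[x,s]) * F[x,s]
    values = P.T @ Fu + D.T @ (pdui * Fu)
    return pd.DataFrame(values, index=families, columns=samples)


def delta_numts(
    numts: pd.DataFrame,
    clinical: pd.DataFrame,
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Per-patient tumor-minus-normal change in numTS.

    Patients contribute only when both a tumor and a normal sample are
    present.  The default scale is ``log2(x + 1)`` differences, which keeps
    the change comparable across miRNA families with very different
    absolute site abundances; ``transform="raw"`` gives plain differences.
    """
    if transform not in ("log2p1", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    clin = clinical.loc[clinical["sample_id"].isin(numts.columns)]
    tumor = (clin[clin["tissue"] == "tumor"]
             .drop_duplicates("patient_id").set_index("patient_id")["sample_id"])
    normal = (clin[clin["tissue"] == "normal"]
              .drop_duplicates("patient_id").set_index("patient_id")["sample_id"])
    patients = tumor.index.intersection(normal.index)
    if len(patients) == 0:
        raise ValidationError("delta_numts: no patients with a tumor/normal pair")
    T = numts[tumor.loc[patients].to_numpy()].to_numpy(dtype=float)
    N = numts[normal.loc[patients].to_numpy()].to_numpy(dtype=float)
    if transform == "log2p1":
        T, N = np.log2(T + 1.0), np.log2(N + 1.0)
    return pd.DataFrame(T - N, index=numts.index, columns=patients)
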