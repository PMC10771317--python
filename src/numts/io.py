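"""Readers, writers and validators for every table the pipeline touches.

All tabular inputs are plain TSV with a header row.  Feature-by-sample
matrices (gene FPKM, miRNA-family TPM, numTS) carry feature IDs in the
first column and sample IDs in the header.  APA tables follow the DaPars
result dialect: a composite gene ID (``gene|transcript|chr|strand``) or a
plain gene ID, a ``Loci`` column (``chr:start-end``, 1-based inclusive),
the predicted proximal polyA coordinate, and one PDUI column per sample.

Coordinates are converted at this boundary to transcript-local, 0-based,
half-open offsets within the 3'UTR (position 0 = 5' end of the UTR in
transcript orientation), so downstream code never sees genomic strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ApaTable",
    "read_matrix",
    "write_matrix",
    "read_apa_table",
    "write_apa_table",
    "read_sites",
    "write_sites",
    "read_clinical",
    "write_clinical",
    "read_family_map",
    "aggregate_by_family",
    "align_samples",
    "filter_mirna_families",
]

MATRIX_KINDS = ("gene_expr", "mirna_expr", "numts")

TISSUE_VOCAB = {"tumor", "normal"}
RESPONSE_VOCAB = {"responder", "non-responder"}
TIMEPOINT_VOCAB = {"pre", "post"}


class FormatError(ValueError):
    """Structurally malformed file (bad header, missing columns)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a table invariant."""


# ---------------------------------------------------------------------------
# feature x sample matrices
# ---------------------------------------------------------------------------

def _check_matrix(df: pd.DataFrame, kind: str, allow_negative: bool = False) -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{kind}: duplicate feature ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{kind}: duplicate sample ID {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(t, np.number) for t in df.dtypes]
        ][0]
        raise ValidationError(f"{kind}: non-numeric values in column {bad!r}")
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{kind}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"{kind}: non-finite value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if not allow_negative and (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{kind}: negative value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return df


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix of the given *kind*.

    Parameters
    ----------
    path : str or path-like
    kind : {"gene_expr", "mirna_expr", "numts", "delta_numts", "outcome"}
        ``delta_numts`` and ``outcome`` values may be negative; the three
        abundance kinds must be non-negative.

    Returns
    -------
    pandas.DataFrame, features as index, samples as columns.
    """
    allow_negative = kind in ("delta_numts", "outcome")
    if not allow_negative and kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{kind}: cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{kind}: no sample columns in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValidationError(f"{kind}: non-numeric values in column {col!r}")
    return _check_matrix(df.astype(float), kind, allow_negative=allow_negative)


def write_matrix(df: pd.DataFrame, path, kind: str = "numts",
                 provenance: str | None = None) -> None:
    """Write a feature-by-sample matrix as TSV (optionally with a '#' header)."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# APA table
# ---------------------------------------------------------------------------

@dataclass
class ApaTable:
    """Per-gene 3'UTR locus, proximal polyA boundary and per-sample PDUI.

    Attributes
    ----------
    loci : DataFrame indexed by gene_id with columns
        ``chrom, start, end, strand, boundary, utr_length``.  ``start``/``end``
        are genomic 0-based half-open; ``boundary`` is the transcript-local
        offset (bases of constitutive pUTR); ``utr_length`` = end - start.
    pdui : DataFrame gene_id x sample of PDUI in [0, 1]; NaN marks missing.
    """

    loci: pd.DataFrame
    pdui: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.loci.index.equals(self.pdui.index):
            raise ValidationError("ApaTable: loci and pdui gene sets differ")
        if self.loci.index.has_duplicates:
            dup = self.loci.index[self.loci.index.duplicated()][0]
            raise ValidationError(f"ApaTable: duplicate gene {dup!r}")
        vals = self.pdui.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                "ApaTable: PDUI outside [0, 1] at gene "
                f"{self.pdui.index[r]!r}, sample {self.pdui.columns[c]!r}"
            )
        b = self.loci["boundary"].to_numpy()
        L = self.loci["utr_length"].to_numpy()
        out = (b <= 0) | (b >= L)
        if out.any():
            g = self.loci.index[np.argwhere(out)[0][0]]
            raise ValidationError(
                f"ApaTable: proximal boundary outside locus for gene {g!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.loci.index

    @property
    def samples(self) -> pd.Index:
        return self.pdui.columns

    def restrict_samples(self, samples: Sequence[str]) -> "ApaTable":
        return ApaTable(self.loci, self.pdui.loc[:, list(samples)])


_APA_META = {"gene", "loci", "proximal_apa", "strand", "fit_value"}


def read_apa_table(path) -> ApaTable:
    """Read a DaPars-dialect APA table.

    Expected columns (case-insensitive): ``Gene`` (plain or DaPars composite
    ``gene|transcript|chr|strand``), ``Loci`` (``chr:start-end``, 1-based
    inclusive), ``Predicted_Proximal_APA`` (genomic coordinate, 1-based),
    optional ``strand``; every remaining column is a sample's PDUI
    (NA = missing).  Genomic input is converted to transcript-local 0-based
    half-open offsets; minus-strand loci are flipped so position 0 is the
    5' end of the UTR in transcript orientation.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    colmap = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key == "gene":
            colmap[col] = "gene"
        elif key == "loci":
            colmap[col] = "loci"
        elif key in ("predicted_proximal_apa", "proximal_apa", "proximal_boundary"):
            colmap[col] = "proximal_apa"
        elif key == "strand":
            colmap[col] = "strand"
        elif key == "fit_value":
            colmap[col] = "fit_value"
    raw = raw.rename(columns=colmap)
    for required in ("gene", "loci", "proximal_apa"):
        if required not in raw.columns:
            raise FormatError(f"APA table missing column {required!r}")

    gene_ids, strands = [], []
    for token in raw["gene"]:
        parts = str(token).split("|")
        gene_ids.append(parts[0])
        strands.append(parts[3] if len(parts) >= 4 else None)
    if "strand" in raw.columns:
        strands = [s if s is not None else t for s, t in zip(strands, raw["strand"])]
    strands = [s if s in ("+", "-") else "+" for s in strands]

    chroms, starts, ends = [], [], []
    for locus in raw["loci"]:
        try:
            chrom, span = str(locus).split(":")
            lo, hi = span.split("-")
            lo_i, hi_i = int(lo), int(hi)
        except ValueError as exc:
            raise FormatError(f"APA table: malformed locus {locus!r}") from exc
        chroms.append(chrom)
        starts.append(lo_i - 1)  # 1-based inclusive -> 0-based half-open
        ends.append(hi_i)

    prox = raw["proximal_apa"].astype(float).astype(int).to_numpy()
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    length = ends - starts
    boundary = np.where(
        np.asarray(strands) == "+",
        prox - starts,        # bases [start, prox] inclusive = prox - (start+1) + 1
        ends - prox + 1,      # transcript runs end -> start on minus strand
    )

    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "strand": strands,
            "boundary": boundary,
            "utr_length": length,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    sample_cols = [c for c in raw.columns if c not in _APA_META]
    if not sample_cols:
        raise FormatError("APA table has no PDUI sample columns")
    pdui = raw[sample_cols].apply(pd.to_numeric, errors="coerce")
    # distinguish true NA from unparseable text
    for col in sample_cols:
        txt = raw[col].astype(str).str.strip()
        parse_failed = pdui[col].isna() & ~txt.isin(["NA", "NaN", "nan", "", "None"])
        if parse_failed.any():
            g = gene_ids[int(np.argwhere(parse_failed.to_numpy())[0][0])]
            raise ValidationError(
                f"APA table: non-numeric PDUI at gene {g!r}, sample {col!r}"
            )
    pdui.index = loci.index
    if loci.index.has_duplicates:
        dup = loci.index[loci.index.duplicated()][0]
        raise ValidationError(f"APA table: duplicate gene {dup!r}")
    return ApaTable(loci, pdui)


def write_apa_table(apa: ApaTable, path, provenance: str | None = None) -> None:
    """Write an :class:`ApaTable` back to the DaPars-dialect TSV."""
    loci = apa.loci
    plus = loci["strand"] == "+"
    prox = np.where(plus, loci["start"] + loci["boundary"],
                    loci["end"] - loci["boundary"] + 1)
    out = pd.DataFrame(
        {
            "Gene": loci.index,
            "Loci": [
                f"{c}:{s + 1}-{e}"
                for c, s, e in zip(loci["chrom"], loci["start"], loci["end"])
            ],
            "strand": loci["strand"].to_numpy(),
            "Predicted_Proximal_APA": prox,
        }
    )
    out = pd.concat([out.reset_index(drop=True),
                     apa.pdui.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# target sites
# ---------------------------------------------------------------------------

def read_sites(path) -> pd.DataFrame:
    """Read a target-site table, either per-site intervals or precomputed counts.

    Interval form: columns ``gene_id, mirna_family, site_start, site_end``
    with 1-based inclusive positions in the 3'UTR coordinate frame
    (converted here to 0-based half-open).  Count form: columns
    ``gene_id, mirna_family, putr_count, dutr_count``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = set(df.columns)
    if {"gene_id", "mirna_family", "site_start", "site_end"} <= cols:
        out = df[["gene_id", "mirna_family", "site_start", "site_end"]].copy()
        out["site_start"] = out["site_start"].astype(int) - 1
        out["site_end"] = out["site_end"].astype(int)
        if (out["site_start"] >= out["site_end"]).any():
            bad = out[out["site_start"] >= out["site_end"]].iloc[0]
            raise ValidationError(
                f"site table: empty/inverted interval for gene {bad['gene_id']!r}"
            )
        return out
    if {"gene_id", "mirna_family", "putr_count", "dutr_count"} <= cols:
        out = df[["gene_id", "mirna_family", "putr_count", "dutr_count"]].copy()
        counts = out[["putr_count", "dutr_count"]].to_numpy()
        if (counts < 0).any() or not np.array_equal(counts, counts.astype(int)):
            raise ValidationError("site table: counts must be non-negative integers")
        out[["putr_count", "dutr_count"]] = counts.astype(int)
        if out.duplicated(["gene_id", "mirna_family"]).any():
            bad = out[out.duplicated(["gene_id", "mirna_family"])].iloc[0]
            raise ValidationError(
                "site table: duplicate (gene, family) pair "
                f"({bad['gene_id']!r}, {bad['mirna_family']!r})"
            )
        return out
    raise FormatError(
        "site table must have (gene_id, mirna_family, site_start, site_end) "
        "or (gene_id, mirna_family, putr_count, dutr_count) columns"
    )


def write_sites(sites: pd.DataFrame, path, provenance: str | None = None) -> None:
    out = sites.copy()
    if "site_start" in out.columns:
        out["site_start"] = out["site_start"].astype(int) + 1  # back to 1-based
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

_CLINICAL_REQUIRED = ("sample_id", "patient_id", "tissue")


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table (one row per sample), validating vocabulary."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str,
                                                         "patient_id": str})
    for col in _CLINICAL_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"clinical table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"clinical table: duplicate sample {dup!r}")
    bad = ~df["tissue"].isin(TISSUE_VOCAB)
    if bad.any():
        raise ValidationError(
            f"clinical table: tissue must be one of {sorted(TISSUE_VOCAB)}, "
            f"got {df.loc[bad, 'tissue'].iloc[0]!r}"
        )
    if "surv_time" in df.columns:
        t = pd.to_numeric(df["surv_time"], errors="raise")
        if (t.dropna() < 0).any():
            raise ValidationError("clinical table: negative surv_time")
        df["surv_time"] = t
    if "event" in df.columns:
        ev = df["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValidationError("clinical table: event must be 0/1")
    for col, vocab in (("response", RESPONSE_VOCAB), ("timepoint", TIMEPOINT_VOCAB)):
        if col in df.columns:
            bad = df[col].notna() & ~df[col].isin(vocab)
            if bad.any():
                raise ValidationError(
                    f"clinical table: {col} must be one of {sorted(vocab)}"
                )
    return df.set_index("sample_id", drop=False)


def write_clinical(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# miRNA -> family map
# ---------------------------------------------------------------------------

def read_family_map(path) -> pd.Series:
    """Read a two-column TSV mapping mirna_id -> family_id.

    Every miRNA must map to exactly one family; families group miRNAs
    sharing a seed sequence and are the feature unit throughout.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("mirna_id", "family_id"):
        if col not in df.columns:
            raise FormatError(f"family map missing column {col!r}")
    dup = df[df["mirna_id"].duplicated(keep=False)]
    if len(dup) and dup.groupby("mirna_id")["family_id"].nunique().gt(1).any():
        bad = dup.groupby("mirna_id")["family_id"].nunique()
        raise ValidationError(
            f"family map: miRNA {bad.index[bad > 1][0]!r} maps to multiple families"
        )
    return df.drop_duplicates("mirna_id").set_index("mirna_id")["family_id"]


def aggregate_by_family(expr: pd.DataFrame, family_map: pd.Series,
                        agg: str = "mean") -> pd.DataFrame:
    """Collapse a per-miRNA expression matrix to family level.

    miRNAs absent from the map are dropped; rows sharing a family are
    combined with the given aggregation (mean by default, matching the
    family-average TPM convention used by the expression filter).
    """
    known = expr.index.intersection(family_map.index)
    sub = expr.loc[known]
    fam = family_map.loc[known]
    out = sub.groupby(fam.to_numpy()).agg(agg)
    out.index.name = "mirna_family"
    return out


# ---------------------------------------------------------------------------
# sample alignment and family filtering
# ---------------------------------------------------------------------------

def _table_samples(table) -> pd.Index:
    if isinstance(table, ApaTable):
        return table.samples
    if isinstance(table, pd.DataFrame):
        if "sample_id" in table.columns:
            return pd.Index(table["sample_id"])
        return table.columns
    raise TypeError(f"cannot align object of type {type(table).__name__}")


def _restrict(table, samples: list):
    if isinstance(table, ApaTable):
        return table.restrict_samples(samples)
    if "sample_id" in getattr(table, "columns", []):
        out = table.set_index("sample_id", drop=False).loc[samples]
        out.index.name = "sample_id"
        return out
    return table.loc[:, samples]


def align_samples(tables: Iterable, mode: str = "intersect") -> list:
    """Restrict every table to a common, canonically ordered sample set.

    ``intersect`` keeps the intersection in the first table's order;
    ``strict`` raises unless all tables already share one sample set.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("align_samples needs at least two tables")
    sample_sets = [set(_table_samples(t)) for t in tables]
    if mode == "strict":
        if any(s != sample_sets[0] for s in sample_sets[1:]):
            raise ValidationError("align_samples(strict): sample sets differ")
    elif mode != "intersect":
        raise ValueError(f"unknown mode {mode!r}")
    common = set.intersection(*sample_sets)
    if not common:
        raise ValidationError("align_samples: empty sample intersection")
    order = [s for s in _table_samples(tables[0]) if s in common]
    return [_restrict(t, order) for t in tables]


def filter_mirna_families(expr: pd.DataFrame, min_mean_tpm: float = 0.01) -> pd.DataFrame:
    """Keep miRNA families whose mean TPM across samples is >= the threshold.

    The cutoff is inclusive, so a family sitting exactly at the default
    0.01 TPM survives.  Row order is preserved.
    """
    keep = expr.mean(axis=1) >= min_mean_tpm
    return expr.loc[keep]
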