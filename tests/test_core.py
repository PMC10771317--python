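import numpy as np
import pandas as pd
import pytest

from _oracles import numts_bruteforce
from conftest import random_instance
from numts import core
from numts.io import ApaTable, ValidationError


def _single_gene_apa(boundary=100, utr_length=500, pdui=0.25, samples=("s1",)):
    loci = pd.DataFrame(
        {"chrom": "chr1", "start": 0, "end": utr_length, "strand": "+",
         "boundary": boundary, "utr_length": utr_length},
        index=pd.Index(["g1"], name="gene_id"),
    )
    pdui_df = pd.DataFrame([[pdui] * len(samples)], index=loci.index,
                           columns=list(samples))
    return ApaTable(loci, pdui_df)


class TestSiteAbundance:
    @pytest.mark.parametrize(
        "putr,dutr,pdui,fpkm,expected",
        [
            (2, 3, 0.0, 1.0, 2.0),    # proximal-only isoform: constitutive sites
            (2, 3, 1.0, 1.0, 5.0),    # full-length isoform: all sites
            (1, 4, 0.25, 10.0, 20.0),
        ],
    )
    def test_weighted_abundance(self, putr, dutr, pdui, fpkm, expected):
        assert core.gene_family_site_abundance(putr, dutr, pdui, fpkm) == expected

    @pytest.mark.parametrize("pdui", [-0.1, 1.1])
    def test_pdui_domain_error(self, pdui):
        with pytest.raises(ValueError):
            core.gene_family_site_abundance(1, 1, pdui, 1.0)


class TestPartitionSites:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "mirna_family",
                                           "site_start", "site_end"])

    def test_proximal_distal_and_straddling(self):
        apa = _single_gene_apa(boundary=100)
        sites = self._sites([
            ("g1", "famA", 10, 16),    # fully within pUTR
            ("g1", "famA", 150, 156),  # fully within dUTR
            ("g1", "famA", 98, 104),   # straddles the boundary
        ])
        counts = core.partition_sites(sites, apa)
        row = counts.set_index(["gene_id", "mirna_family"]).loc[("g1", "famA")]
        # the straddling site is truncated on the short isoform -> distal
        assert row["putr_count"] == 1
        assert row["dutr_count"] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_isoform_enumeration_oracle(self, seed):
        # a site is carried intact by the short isoform iff it ends at or
        # before the proximal boundary; otherwise only the long isoform
        # carries it
        rng = np.random.default_rng(seed)
        boundary = int(rng.integers(50, 450))
        apa = _single_gene_apa(boundary=boundary)
        starts = rng.integers(0, 493, 50)
        sites = self._sites([("g1", "famA", int(s), int(s) + 7) for s in starts])
        counts = core.partition_sites(sites, apa).iloc[0]
        short_isoform_len, long_isoform_len = boundary, 500
        on_short = sum(1 for s in starts if s + 7 <= short_isoform_len)
        on_long_only = sum(1 for s in starts
                           if s + 7 > short_isoform_len and s + 7 <= long_isoform_len)
        assert counts["putr_count"] == on_short
        assert counts["dutr_count"] == on_long_only

    def test_site_outside_locus_rejected(self):
        apa = _single_gene_apa(utr_length=200)
        with pytest.raises(ValidationError, match="outside"):
            core.partition_sites(self._sites([("g1", "famA", 195, 202)]), apa)

    def test_gene_without_apa_row_counts_as_constitutive(self):
        apa = _single_gene_apa()
        sites = self._sites([("g2", "famA", 400, 407)])  # g2 not in APA table
        counts = core.partition_sites(sites, apa)
        assert counts.iloc[0]["putr_count"] == 1
        assert counts.iloc[0]["dutr_count"] == 0


def _counts(rows):
    return pd.DataFrame(rows, columns=["gene_id", "mirna_family",
                                       "putr_count", "dutr_count"])


class TestNumtsMatrix:
    def test_single_gene_single_family(self):
        apa = _single_gene_apa(pdui=0.25)
        expr = pd.DataFrame([[10.0]], index=pd.Index(["g1"], name="gene_id"),
                            columns=["s1"])
        numts = core.compute_numts_matrix(expr, apa, _counts([("g1", "famA", 1, 4)]))
        assert numts.loc["famA", "s1"] == pytest.approx(20.0)

    def test_additivity_over_genes(self):
        loci = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1000], "end": [500, 1500],
             "strand": "+", "boundary": [100, 100], "utr_length": 500},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        apa = ApaTable(loci, pd.DataFrame([[0.25], [0.0]], index=loci.index,
                                          columns=["s1"]))
        expr = pd.DataFrame([[10.0], [1.0]], index=loci.index, columns=["s1"])
        numts = core.compute_numts_matrix(
            expr, apa, _counts([("g1", "famA", 1, 4), ("g2", "famA", 2, 5)]))
        assert numts.loc["famA", "s1"] == pytest.approx(22.0)

    def test_no_gene_overlap_errors(self):
        apa = _single_gene_apa()
        expr = pd.DataFrame([[1.0]], index=pd.Index(["g1"], name="gene_id"),
                            columns=["s1"])
        with pytest.raises(ValidationError, match="no overlap"):
            core.compute_numts_matrix(expr, apa, _counts([("gX", "famA", 1, 1)]))

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("missing", ["skip", "mean"])
    def test_matches_per_site_bruteforce_oracle(self, seed, missing):
        expr, apa, sites = random_instance(seed)
        counts = core.partition_sites(sites, apa)
        fast = core.compute_numts_matrix(expr, apa, counts, missing_pdui=missing)
        slow = numts_bruteforce(expr, apa, sites, missing_pdui=missing)
        slow = slow.loc[fast.index, fast.columns]
        assert np.allclose(fast.to_numpy(), slow.to_numpy(), atol=1e-9)


class TestNumtsProperties:
    def _setup(self, seed):
        expr, apa, sites = random_instance(seed, frac_missing_pdui=0.0)
        counts = core.partition_sites(sites, apa)
        return expr, apa, counts

    def test_monotone_in_pdui(self):
        expr, apa, counts = self._setup(7)
        base = core.compute_numts_matrix(expr, apa, counts)
        bumped = ApaTable(apa.loci, (apa.pdui + 0.05).clip(upper=1.0))
        up = core.compute_numts_matrix(expr, apa=bumped, counts=counts)
        assert (up.to_numpy() >= base.to_numpy() - 1e-12).all()

    def test_homogeneous_in_fpkm(self):
        expr, apa, counts = self._setup(8)
        base = core.compute_numts_matrix(expr, apa, counts)
        scaled = core.compute_numts_matrix(expr * 3.0, apa, counts)
        assert np.allclose(scaled.to_numpy(), 3.0 * base.to_numpy(), rtol=1e-12)

    def test_pdui_limits_reduce_to_plain_counting(self):
        expr, apa, counts = self._setup(9)
        ones = ApaTable(apa.loci, apa.pdui * 0 + 1.0)
        zeros = ApaTable(apa.loci, apa.pdui * 0)
        at_one = core.compute_numts_matrix(expr, ones, counts)
        at_zero = core.compute_numts_matrix(expr, zeros, counts)
        # with PDUI = 1 every site counts; with PDUI = 0 only pUTR sites
        total = counts.assign(total=counts.putr_count + counts.dutr_count)
        for fam in at_one.index:
            sub = total[total.mirna_family == fam]
            exp_one = sum(
                row.total * expr.loc[row.gene_id]
                for row in sub.itertuples()
            )
            exp_zero = sum(
                row.putr_count * expr.loc[row.gene_id]
                for row in sub.itertuples()
            )
            assert np.allclose(at_one.loc[fam], exp_one, atol=1e-9)
            assert np.allclose(at_zero.loc[fam], exp_zero, atol=1e-9)


class TestDeltaNumts:
    def _clinical(self, patients):
        rows = []
        for p in patients:
            rows.append((f"{p}_T", p, "tumor"))
            rows.append((f"{p}_N", p, "normal"))
        return pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue"])

    def test_identical_pair_gives_zero(self):
        numts = pd.DataFrame([[3.0, 3.0]], index=["famA"],
                             columns=["P1_T", "P1_N"])
        delta = core.delta_numts(numts, self._clinical(["P1"]))
        assert delta.loc["famA", "P1"] == 0.0

    def test_log2_difference_scale(self):
        numts = pd.DataFrame([[3.0, 1.0]], index=["famA"],
                             columns=["P1_T", "P1_N"])
        delta = core.delta_numts(numts, self._clinical(["P1"]))
        assert delta.loc["famA", "P1"] == pytest.approx(np.log2(4) - np.log2(2))

    def test_raw_scale_flag(self):
        numts = pd.DataFrame([[3.0, 1.0]], index=["famA"],
                             columns=["P1_T", "P1_N"])
        delta = core.delta_numts(numts, self._clinical(["P1"]), transform="raw")
        assert delta.loc["famA", "P1"] == 2.0

    def test_matches_per_patient_loop_oracle(self):
        rng = np.random.default_rng(5)
        patients = [f"P{i}" for i in range(6)]
        cols = [f"{p}_{t}" for p in patients for t in ("T", "N")]
        numts = pd.DataFrame(rng.uniform(0, 100, (4, len(cols))),
                             index=[f"fam{i}" for i in range(4)], columns=cols)
        delta = core.delta_numts(numts, self._clinical(patients))
        for p in patients:
            for fam in numts.index:
                expected = (np.log2(numts.loc[fam, f"{p}_T"] + 1)
                            - np.log2(numts.loc[fam, f"{p}_N"] + 1))
                assert delta.loc[fam, p] == pytest.approx(expected)

    def test_unpaired_patients_dropped_and_empty_errors(self):
        numts = pd.DataFrame([[1.0, 2.0]], index=["famA"],
                             columns=["P1_T", "P2_N"])
        clin = pd.DataFrame(
            [("P1_T", "P1", "tumor"), ("P2_N", "P2", "normal")],
            columns=["sample_id", "patient_id", "tissue"])
        with pytest.raises(ValidationError, match="pair"):
            core.delta_numts(numts, clin)
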