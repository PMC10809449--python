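"""Variant application, epitope enumeration, and the filter chain."""

import numpy as np
import pytest

from oran.neoantigen_caller import (
    EpitopeCandidate,
    FilterThresholds,
    MutantProtein,
    Variant,
    VariantRejection,
    apply_variant,
    enumerate_epitopes,
    rna_expressed,
    select_neoantigens,
)
from oran.reference_model import TranscriptModel, translate

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def _tx(cds, strand="+", chrom="chr1"):
    if strand == "+":
        genome_piece = cds
    else:
        from oran.reference_model import reverse_complement
        genome_piece = reverse_complement(cds)
    return TranscriptModel("T1", "G1", "GENE1", chrom, strand,
                           ((0, len(cds)),), cds, translate(cds))


class TestApplyVariant:
    def test_missense_snv(self):
        t = _tx("ATGGCTTGA")
        m = apply_variant(t, Variant("chr1", 5, "C", "G", vaf=0.9))
        assert (m.wildtype_protein, m.mutant_protein) == ("MA", "MG")
        assert m.altered_range == (1, 2)
        assert m.consequence == "missense"

    def test_synonymous_snv_flagged_non_antigenic(self):
        t = _tx("ATGGCTTGA")
        m = apply_variant(t, Variant("chr1", 6, "T", "C", vaf=0.9))  # GCT>GCC
        assert m.altered_range == (0, 0)
        assert not m.is_antigenic

    def test_frameshift_matches_retranslation_oracle(self):
        cds = "ATGAAACCCGGGTTTAGACTTTGA"
        t = _tx(cds)
        v = Variant("chr1", 3, "G", "GA", vaf=0.9)  # 1-nt ins after base 3
        m = apply_variant(t, v)
        mutant_cds = cds[:3] + "A" + cds[3:]
        assert m.mutant_protein == translate(mutant_cds)
        # novel tail: every residue from the shift to the new C-terminus
        assert m.mutant_protein == "MKTRV"
        assert m.altered_range == (2, len(m.mutant_protein))
        assert m.consequence == "frameshift"

    def test_inframe_insertion(self):
        t = _tx("ATGGCTAAATGA")  # M A K
        v = Variant("chr1", 6, "T", "TGAA", vaf=0.9)  # +GAA after codon 2
        m = apply_variant(t, v)
        assert m.mutant_protein == "MAEK"
        assert m.altered_range == (2, 3)

    def test_inframe_deletion_marks_junction(self):
        t = _tx("ATGGCTAAATGA")  # M A K
        v = Variant("chr1", 3, "GGCT", "G", vaf=0.9)  # remove codon GCT
        m = apply_variant(t, v)
        assert m.mutant_protein == "MK"
        assert m.is_antigenic

    def test_minus_strand_snv(self):
        t = _tx("ATGGCTTGA", strand="-")
        # CDS base 5 is C; on the plus strand that's G>C at mirrored pos
        # genome = revcomp(ATGGCTTGA) = TCAAGCCAT; CDS index 4 -> plus idx 4
        m = apply_variant(t, Variant("chr1", 5, "G", "C", vaf=0.9))
        assert m.mutant_protein == "MG"

    def test_utr_variant_rejected_with_reason(self):
        t = _tx("ATGGCTTGA")
        with pytest.raises(VariantRejection, match="outside_cds"):
            apply_variant(t, Variant("chr1", 500, "A", "T", vaf=0.9))

    def test_ref_mismatch_is_hard_error(self):
        t = _tx("ATGGCTTGA")
        with pytest.raises(ValueError, match="ref mismatch"):
            apply_variant(t, Variant("chr1", 5, "A", "G", vaf=0.9))

    def test_stop_gain_rejected(self):
        t = _tx("ATGAAAGCTTGA")  # M K A
        with pytest.raises(VariantRejection, match="stop_gain"):
            apply_variant(t, Variant("chr1", 4, "A", "T", vaf=0.9))  # AAA>TAA

    def test_stop_loss_retranslates_through_utr(self):
        t = TranscriptModel("T1", "G1", "GENE1", "chr1", "+", ((0, 9),),
                            "ATGGCTTGA", "MA", utr3_sequence="AAATAG")
        m = apply_variant(t, Variant("chr1", 7, "T", "C", vaf=0.9))  # TGA>CGA
        assert m.mutant_protein == "MARK"
        assert m.altered_range == (2, 4)
        assert m.consequence == "stop_loss"


def test_rna_expressed_inclusive_threshold():
    thr = FilterThresholds()
    assert rna_expressed(Variant("c", 1, "A", "T", 0.7, rna_alt_reads=3), thr)
    assert not rna_expressed(Variant("c", 1, "A", "T", 0.7, 0), thr)
    thr5 = FilterThresholds(min_rna_alt_reads=5)
    assert rna_expressed(Variant("c", 1, "A", "T", 0.7, 5), thr5)


class TestEnumerateEpitopes:
    def _mutant(self, length, altered, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        wt = "".join(rng.choice(AAS, size=length))
        lo, hi = altered
        mut = list(wt)
        for i in range(lo, hi):
            mut[i] = "W" if wt[i] != "W" else "Y"
        return MutantProtein("T1", "G1", wt, "".join(mut), altered, "missense")

    def test_single_substitution_window_count(self):
        m = self._mutant(20, (9, 10))  # residue 10, 1-based
        thr = FilterThresholds(class1_lengths=(9,), class2_length=15)
        class1 = [w for w in enumerate_epitopes(m, thr) if w.mhc_class == "I"]
        assert len(class1) == 9
        assert [w.start for w in class1] == list(range(1, 10))

    def test_substitution_at_first_residue(self):
        m = self._mutant(20, (0, 1))
        thr = FilterThresholds(class1_lengths=(9,), class2_length=15)
        class1 = [w for w in enumerate_epitopes(m, thr) if w.mhc_class == "I"]
        assert len(class1) == 1

    def test_frameshift_tail_boundary(self):
        m = self._mutant(12, (6, 12))
        thr = FilterThresholds(class1_lengths=(8,), class2_length=15)
        class1 = [w for w in enumerate_epitopes(m, thr) if w.mhc_class == "I"]
        assert [w.start for w in class1] == [0, 1, 2, 3, 4]

    def test_short_protein_contributes_nothing(self):
        m = self._mutant(6, (2, 3))
        thr = FilterThresholds(class1_lengths=(8,), class2_length=15)
        assert enumerate_epitopes(m, thr) == []

    def test_matches_naive_oracle_on_random_mutants(self):
        """Windows equal brute-force: all substrings of the mutant that
        overlap the altered span and are absent from the wild type."""
        rng = np.random.default_rng(11)
        thr = FilterThresholds()
        for _ in range(200):
            n = int(rng.integers(9, 40))
            lo = int(rng.integers(0, n))
            hi = int(rng.integers(lo + 1, n + 1))
            m = self._mutant(n, (lo, hi), rng_seed=int(rng.integers(1 << 30)))
            got = {(w.peptide, w.start, w.mhc_class)
                   for w in enumerate_epitopes(m, thr)}
            naive = set()
            for mhc, ks in (("I", thr.class1_lengths),
                            ("II", (thr.class2_length,))):
                for k in ks:
                    for i in range(len(m.mutant_protein) - k + 1):
                        window = m.mutant_protein[i:i + k]
                        overlaps = i < hi and i + k > lo
                        if overlaps and window not in m.wildtype_protein:
                            naive.add((window, i, mhc))
            assert got == naive


def _cand(**kw):
    base = dict(peptide="A" * 9, mhc_class="I", allele="toy-Kb",
                gene_id="G1", transcript_id="T1", source="neoantigen",
                affinity_nm=100.0, tumor_tpm=5.0, vaf=0.9)
    base.update(kw)
    return EpitopeCandidate(**base)


class TestSelectNeoantigens:
    thr = FilterThresholds()

    def test_class1_within_all_thresholds_retained(self):
        kept, rej = select_neoantigens(
            [_cand(affinity_nm=499.0, vaf=0.7, tumor_tpm=2.0)], self.thr)
        assert len(kept) == 1 and not rej

    def test_affinity_boundary_strict(self):
        kept, rej = select_neoantigens(
            [_cand(affinity_nm=500.0, vaf=0.9, tumor_tpm=5.0)], self.thr)
        assert not kept and list(rej.values()) == ["affinity"]

    def test_class2_cutoff_1000(self):
        kept, _ = select_neoantigens(
            [_cand(peptide="A" * 15, mhc_class="II", allele="toy-IAb",
                   affinity_nm=800.0, vaf=0.61, tumor_tpm=1.01)], self.thr)
        assert len(kept) == 1

    def test_vaf_boundary_strict(self):
        kept, rej = select_neoantigens(
            [_cand(affinity_nm=100.0, vaf=0.6, tumor_tpm=2.0)], self.thr)
        assert not kept and list(rej.values()) == ["VAF"]

    def test_tpm_boundary_strict(self):
        kept, rej = select_neoantigens(
            [_cand(tumor_tpm=1.0)], self.thr)
        assert not kept and list(rej.values()) == ["expression"]

    def test_first_failed_step_reported(self):
        kept, rej = select_neoantigens(
            [_cand(affinity_nm=900.0, vaf=0.1, tumor_tpm=0.0)], self.thr)
        assert list(rej.values()) == ["affinity"]

    def test_missing_affinity_is_error(self):
        with pytest.raises(ValueError, match="affinity"):
            select_neoantigens([_cand(affinity_nm=None)], self.thr)

    def test_taa_candidates_skip_vaf(self):
        kept, _ = select_neoantigens(
            [_cand(vaf=None, source="TAA")], self.thr)
        assert len(kept) == 1

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        cands = [_cand(peptide="".join(rng.choice(AAS, size=9)),
                       affinity_nm=float(rng.uniform(1, 2000)),
                       vaf=float(rng.uniform(0, 1)),
                       tumor_tpm=float(rng.uniform(0, 10)))
                 for _ in range(50)]
        kept1, _ = select_neoantigens(cands, self.thr)
        kept2, _ = select_neoantigens(list(reversed(cands)), self.thr)
        assert set(kept1) == set(kept2)

    def test_tightening_thresholds_is_monotone(self):
        rng = np.random.default_rng(5)
        cands = [_cand(peptide="".join(rng.choice(AAS, size=9)),
                       affinity_nm=float(rng.uniform(1, 2000)),
                       vaf=float(rng.uniform(0, 1)),
                       tumor_tpm=float(rng.uniform(0, 10)))
                 for _ in range(100)]
        base, _ = select_neoantigens(cands, self.thr)
        for tighter in [
            FilterThresholds(max_affinity_class1=200),
            FilterThresholds(min_vaf=0.8),
            FilterThresholds(min_tpm=3.0),
        ]:
            subset, _ = select_neoantigens(cands, tighter)
            assert set(subset) <= set(base)
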