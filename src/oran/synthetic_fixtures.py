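"""Self-contained synthetic datasets with the statistical structure the
antigen pipeline assumes.

The generator emits a toy genome/annotation/proteome, somatic variants
spiked with known outcomes (a truth table states which spikes must
survive the whole filter chain and which must fail at exactly one named
step), a tumor-replicate vs normal-tissue-panel expression matrix with
designated overexpressed transcripts, and a pre/post capture-enrichment
expression pair with known capture efficiencies.

Every generator is a pure function of its spec (seed included): the
same spec always produces byte-identical files. Spiked "pass"
neoantigens are constructed against the packaged surrogate binding
matrices — the wild-type context is one substitution away from a
surrogate consensus peptide and the spiked variant completes it — so
end-to-end tests need no external predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mhc_binding import SurrogatePredictor
from .neoantigen_caller import (
    FilterThresholds,
    Variant,
    apply_variant,
    enumerate_epitopes,
)
from .reference_model import (
    CODON_TABLE,
    STOP_CODONS,
    TranscriptModel,
    reverse_complement,
    translate,
)
from .taa_caller import TPM_TOTAL, ExpressionMatrix

AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    AA_TO_CODONS.setdefault(aa, []).append(codon)
NON_STOP_CODONS = sorted(CODON_TABLE)
AMINO_ACIDS = sorted(AA_TO_CODONS)
NT = "ACGT"


@dataclass(frozen=True)
class NeoSpike:
    """One planned somatic spike: its designed outcome flag
    ("pass", "fail:<step>", or "synonymous") and variant shape."""

    flag: str
    variant_class: str  # SNV | inframe_insertion | frameshift
    strand: str = "+"


DEFAULT_NEO_SPIKES: tuple[NeoSpike, ...] = (
    NeoSpike("pass", "SNV", "+"),
    NeoSpike("pass", "SNV", "-"),
    NeoSpike("pass", "inframe_insertion", "+"),
    NeoSpike("pass", "frameshift", "+"),
    NeoSpike("fail:affinity", "SNV", "+"),
    NeoSpike("fail:VAF", "SNV", "+"),
    NeoSpike("fail:expression", "SNV", "+"),
    NeoSpike("fail:RNA", "SNV", "+"),
    NeoSpike("synonymous", "SNV", "+"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the source study design: 3 tumor replicates, a
    95-tissue normal panel, and small gene counts so the whole suite
    runs in seconds.
    """

    seed: int = 0
    n_genes: int = 20
    isoforms_per_gene: int = 2
    cds_length_range: tuple[int, int] = (150, 270)  # nt, incl. stop
    n_tumor_replicates: int = 3
    n_normal_tissues: int = 95
    n_spiked_taas: int = 3
    neo_spikes: tuple[NeoSpike, ...] = DEFAULT_NEO_SPIKES
    capture_efficiency: float = 0.95
    off_target_efficiency: float = 0.002
    class1_allele: str = "toy-Kb"
    class2_allele: str = "toy-IAb"

    def __post_init__(self) -> None:
        if not (0 < self.off_target_efficiency
                <= self.capture_efficiency <= 1):
            raise ValueError("require 0 < o <= e <= 1")
        if min(self.n_genes, self.isoforms_per_gene,
               self.n_tumor_replicates, self.n_normal_tissues) < 1:
            raise ValueError("counts must be >= 1")
        needed = len(self.neo_spikes) + self.n_spiked_taas + 2
        if self.n_genes < needed + 2:
            raise ValueError(
                f"n_genes={self.n_genes} too small for "
                f"{len(self.neo_spikes)} neo spikes + "
                f"{self.n_spiked_taas} TAA spikes + 2 decoys "
                f"(need >= {needed + 2})"
            )
        lo, hi = self.cds_length_range
        if lo < 120 or hi < lo:
            raise ValueError("cds_length_range must satisfy 120 <= lo <= hi")


@dataclass
class SpikePlan:
    """A fully resolved spiked variant (genomic coordinates, VCF
    alleles, per-variant WES/RNA evidence) plus its truth label."""

    spike: NeoSpike
    gene_id: str
    transcript_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    vaf: float
    rna_alt_reads: int
    tumor_gene_tpm: float

    def to_variant(self) -> Variant:
        return Variant(self.chrom, self.pos, self.ref, self.alt,
                       vaf=self.vaf, rna_alt_reads=self.rna_alt_reads)


@dataclass
class Reference:
    """Generated reference bundle plus the spike/TAA bookkeeping the
    downstream generators need."""

    spec: FixtureSpec
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    spike_plans: list[SpikePlan]
    taa_spike_transcripts: list[str]
    taa_decoy_low_tumor: str
    taa_decoy_normal_sum: str
    tofu_target_genes: set[str]

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.transcript_id == tid)

    def by_gene(self, gid: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.gene_id == gid]


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _backtranslate(rng: np.random.Generator, protein: str) -> list[str]:
    return [AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))]
            for aa in protein]


def _rand_stop(rng: np.random.Generator) -> str:
    stops = sorted(STOP_CODONS)
    return stops[rng.integers(len(stops))]


def _snv_context(rng: np.random.Generator, consensus: str,
                 pos: int) -> tuple[str, str, str, int]:
    """Design a wild-type codon one substitution away from the
    consensus residue at ``pos``.

    Returns (wt_codon, mut_codon, wt_aa, offset_in_codon): mut_codon
    encodes consensus[pos], wt_codon differs at one nucleotide and
    encodes a different, non-stop amino acid.
    """
    target_aa = consensus[pos]
    codons = list(AA_TO_CODONS[target_aa])
    rng.shuffle(codons)
    for mut_codon in codons:
        offsets = list(range(3))
        rng.shuffle(offsets)
        for off in offsets:
            for nt in NT:
                if nt == mut_codon[off]:
                    continue
                wt_codon = mut_codon[:off] + nt + mut_codon[off + 1:]
                if wt_codon in STOP_CODONS:
                    continue
                if CODON_TABLE[wt_codon] != target_aa:
                    return wt_codon, mut_codon, CODON_TABLE[wt_codon], off
    raise RuntimeError(f"no single-nt neighbor found for {target_aa}")


def _cds_index_to_genomic(intervals: tuple[tuple[int, int], ...],
                          strand: str, cds_len: int, i: int) -> int:
    """Genomic position (0-based) of CDS index ``i``."""
    plus_off = i if strand == "+" else cds_len - 1 - i
    for s, e in intervals:
        w = e - s
        if plus_off < w:
            return s + plus_off
        plus_off -= w
    raise IndexError(f"CDS index {i} outside transcript")


def _frameshift_tail(rng: np.random.Generator,
                     consensus: str) -> tuple[str, str]:
    """Design (inserted_nt, downstream_cds) such that a 1-nt insertion
    shifts the frame onto the consensus peptide followed by a stop,
    while the unshifted frame translates cleanly to the wild-type end.
    """
    for _ in range(1000):
        codons = [AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))]
                  for aa in consensus] + [_rand_stop(rng)]
        shifted = "".join(codons)  # X + D, len 3*(len(consensus)+1)
        inserted, d = shifted[0], shifted[1:]
        # unshifted frame over D must be stop-free
        wt_codons = [d[i:i + 3] for i in range(0, len(d) - 2, 3)]
        if any(c in STOP_CODONS for c in wt_codons):
            continue
        leftover = len(d) % 3
        tail = d
        if leftover:
            partial = d[-leftover:]
            for _ in range(50):
                fill = "".join(rng.choice(list(NT), size=3 - leftover))
                if partial + fill not in STOP_CODONS:
                    tail = d + fill
                    break
            else:
                continue
        # a few spacer codons, then the wild-type stop
        spacer = [NON_STOP_CODONS[rng.integers(len(NON_STOP_CODONS))]
                  for _ in range(3)]
        return inserted, tail + "".join(spacer) + _rand_stop(rng)
    raise RuntimeError("frameshift tail search failed")


def _verify_spike(t: TranscriptModel, plan: SpikePlan,
                  spec: FixtureSpec, predictor: SurrogatePredictor) -> bool:
    """Check a spiked variant behaves as designed under the surrogate:
    'pass' has >= 1 window beating the class cutoff, 'fail:affinity'
    has none, 'synonymous' yields no antigenic product."""
    thr = FilterThresholds()
    v = plan.to_variant()
    m = apply_variant(t, v)
    if plan.spike.flag == "synonymous":
        return not m.is_antigenic
    if not m.is_antigenic:
        return False
    windows = enumerate_epitopes(m, thr)
    best_pass = False
    for w in windows:
        allele = (spec.class1_allele if w.mhc_class == "I"
                  else spec.class2_allele)
        nm = predictor.predict(w.peptide, allele)
        cutoff = (thr.max_affinity_class1 if w.mhc_class == "I"
                  else thr.max_affinity_class2)
        if nm < cutoff:
            best_pass = True
    if plan.spike.flag == "fail:affinity":
        return not best_pass
    return best_pass


def make_reference(spec: FixtureSpec) -> Reference:
    """Generate genome FASTA content, transcript models, and the spike
    plans (deterministic in ``spec``)."""
    rng = np.random.default_rng(spec.seed)
    predictor = SurrogatePredictor()
    consensus9 = predictor.consensus(spec.class1_allele, 9)

    n_neo = len(spec.neo_spikes)
    gene_roles: list[str] = (
        [f"neo:{i}" for i in range(n_neo)]
        + [f"taa:{i}" for i in range(spec.n_spiked_taas)]
        + ["taa_decoy_low_tumor", "taa_decoy_normal_sum"]
    )
    gene_roles += ["background"] * (spec.n_genes - len(gene_roles))

    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0

    def _emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        start = cursor
        pieces.append(seq)
        cursor += len(seq)
        return (start, cursor)

    def _spacer() -> None:
        _emit("".join(rng.choice(list(NT), size=int(rng.integers(20, 41)))))

    transcripts: list[TranscriptModel] = []
    spike_plans: list[SpikePlan] = []
    taa_spikes: list[str] = []
    decoy_low = decoy_norm = ""

    for g, role in enumerate(gene_roles):
        gid, gname = f"G{g:03d}", f"GENE{g:03d}"
        tid1 = f"T{g:03d}.1"
        spike = (spec.neo_spikes[int(role.split(":")[1])]
                 if role.startswith("neo:") else None)
        strand = spike.strand if spike else ("+" if rng.random() < 0.5 else "-")

        total_nt = int(rng.integers(*spec.cds_length_range))
        n_res = total_nt // 3 - 1  # minus stop codon
        core_len = max(8, n_res * 2 // 5)
        suffix_len = n_res - 1 - core_len  # minus initiator M
        protein1 = "M" + _rand_protein(rng, core_len) \
                       + _rand_protein(rng, suffix_len)

        # embed the near-consensus context for designed SNV spikes
        ctx_residue_pos = None
        snv_design = None
        suffix_start = 1 + core_len
        if spike and spike.variant_class == "SNV" and spike.flag != "fail:affinity":
            ctx_pos0 = suffix_start + 3  # context start, in suffix
            wt_codon, mut_codon, wt_aa, off = _snv_context(rng, consensus9, 4)
            wt_context = consensus9[:4] + wt_aa + consensus9[5:]
            protein1 = (protein1[:ctx_pos0] + wt_context
                        + protein1[ctx_pos0 + 9:])
            ctx_residue_pos = ctx_pos0 + 4
            snv_design = (wt_codon, mut_codon, off)
        elif spike and spike.variant_class == "inframe_insertion":
            # context lacks consensus position 4; the insertion adds it
            ctx_pos0 = suffix_start + 3
            wt_context = consensus9[:4] + consensus9[5:]  # 8 residues
            protein1 = (protein1[:ctx_pos0] + wt_context
                        + protein1[ctx_pos0 + 8:])
            ctx_residue_pos = ctx_pos0 + 3  # insertion goes after this

        codons1 = _backtranslate(rng, protein1)
        if snv_design is not None:
            codons1[ctx_residue_pos] = snv_design[0]
        cds1 = "".join(codons1) + _rand_stop(rng)

        fs_design = None
        if spike and spike.variant_class == "frameshift":
            k0 = suffix_start + 3
            inserted, downstream = _frameshift_tail(rng, consensus9)
            cds1 = "".join(codons1[:k0]) + downstream
            fs_design = (k0, inserted)
        protein1 = translate(cds1)

        # isoform 2 shares the 5' exon; its own continuation + suffix
        cut = int(rng.integers(6, 3 * min(core_len, len(protein1)) - 3))
        cds2 = None
        if spec.isoforms_per_gene >= 2:
            r = cut % 3
            prefix2 = cds1[:cut]
            if r:
                head = cds1[3 * (cut // 3):cut]
                while True:
                    fill = "".join(rng.choice(list(NT), size=3 - r))
                    if head + fill not in STOP_CODONS:
                        break
                prefix2 += fill
            suffix2 = _backtranslate(rng, _rand_protein(rng, suffix_len))
            cds2 = prefix2 + "".join(suffix2) + _rand_stop(rng)

        # genomic layout: exon A = cds1[:cut], B = cds1[cut:], C = tail2
        _spacer()
        if strand == "+":
            a_iv = _emit(cds1[:cut]); _spacer()
            b_iv = _emit(cds1[cut:]); _spacer()
            t1_ivs = (a_iv, b_iv)
            c_iv = None
            if cds2 is not None:
                c_iv = _emit(cds2[cut:]); _spacer()
                t2_ivs = (a_iv, c_iv)
        else:
            if cds2 is not None:
                c_iv = _emit(reverse_complement(cds2[cut:])); _spacer()
            b_iv = _emit(reverse_complement(cds1[cut:])); _spacer()
            a_iv = _emit(reverse_complement(cds1[:cut])); _spacer()
            t1_ivs = (b_iv, a_iv)
            if cds2 is not None:
                t2_ivs = (c_iv, a_iv)

        t1 = TranscriptModel(tid1, gid, gname, chrom, strand, t1_ivs,
                             cds1, translate(cds1))
        transcripts.append(t1)
        if cds2 is not None:
            if strand == "-":
                t2_ivs = tuple(sorted(t2_ivs))
            transcripts.append(TranscriptModel(
                f"T{g:03d}.2", gid, gname, chrom, strand, t2_ivs,
                cds2, translate(cds2)))

        if role.startswith("taa:"):
            taa_spikes.append(tid1)
        elif role == "taa_decoy_low_tumor":
            decoy_low = tid1
        elif role == "taa_decoy_normal_sum":
            decoy_norm = tid1

        if spike is None:
            continue

        # resolve the spike to genomic VCF coordinates
        flag = spike.flag
        vaf = {"fail:VAF": 0.5}.get(flag, float(rng.uniform(0.7, 0.95)))
        rna = 0 if flag == "fail:RNA" else int(rng.integers(5, 30))
        tumor_tpm = 0.4 if flag == "fail:expression" else float(
            rng.uniform(20, 60))

        if spike.variant_class == "SNV" and flag != "fail:affinity" \
                and flag != "synonymous":
            i = 3 * ctx_residue_pos + snv_design[2]
            gpos = _cds_index_to_genomic(t1_ivs, strand, len(cds1), i)
            ref_c, alt_c = cds1[i], snv_design[1][snv_design[2]]
            if strand == "-":
                ref_c, alt_c = (reverse_complement(ref_c),
                                reverse_complement(alt_c))
            plan = SpikePlan(spike, gid, tid1, chrom, gpos + 1,
                             ref_c, alt_c, vaf, rna, tumor_tpm)
        elif spike.variant_class == "inframe_insertion":
            j = 3 * ctx_residue_pos + 2  # last base of the context codon
            gpos = _cds_index_to_genomic(t1_ivs, strand, len(cds1), j)
            ins_codon = AA_TO_CODONS[consensus9[4]][0]
            plan = SpikePlan(spike, gid, tid1, chrom, gpos + 1,
                             cds1[j], cds1[j] + ins_codon, vaf, rna,
                             tumor_tpm)
        elif spike.variant_class == "frameshift":
            j = 3 * fs_design[0] - 1
            gpos = _cds_index_to_genomic(t1_ivs, strand, len(cds1), j)
            plan = SpikePlan(spike, gid, tid1, chrom, gpos + 1,
                             cds1[j], cds1[j] + fs_design[1], vaf, rna,
                             tumor_tpm)
        elif flag == "synonymous":
            plan = _design_synonymous(rng, t1, vaf, rna, tumor_tpm, spike)
        else:  # fail:affinity — random missense, verified below
            plan = _design_fail_affinity(rng, t1, spec, predictor, vaf,
                                         rna, tumor_tpm, spike)
        spike_plans.append(plan)

    genome = {chrom: "".join(pieces)}
    ref = Reference(
        spec=spec,
        genome=genome,
        transcripts=transcripts,
        spike_plans=spike_plans,
        taa_spike_transcripts=taa_spikes,
        taa_decoy_low_tumor=decoy_low,
        taa_decoy_normal_sum=decoy_norm,
        tofu_target_genes={p.gene_id for p in spike_plans
                           if p.spike.flag == "pass"}
                          | {t.gene_id for t in transcripts
                             if t.transcript_id in set(taa_spikes)},
    )
    _check_reference(ref, predictor)
    return ref


def _design_synonymous(rng, t: TranscriptModel, vaf, rna, tpm,
                       spike: NeoSpike) -> SpikePlan:
    order = rng.permutation(len(t.protein_sequence))
    for ridx in order:
        ridx = int(ridx)
        codon = t.cds_sequence[3 * ridx : 3 * ridx + 3]
        for off in range(3):
            for nt in NT:
                if nt == codon[off]:
                    continue
                alt_codon = codon[:off] + nt + codon[off + 1:]
                if alt_codon not in STOP_CODONS and \
                        CODON_TABLE.get(alt_codon) == CODON_TABLE[codon]:
                    i = 3 * ridx + off
                    gpos = _cds_index_to_genomic(
                        t.exon_intervals, t.strand, t.cds_length, i)
                    ref_c, alt_c = t.cds_sequence[i], nt
                    if t.strand == "-":
                        ref_c = reverse_complement(ref_c)
                        alt_c = reverse_complement(alt_c)
                    return SpikePlan(spike, t.gene_id, t.transcript_id,
                                     t.chrom, gpos + 1, ref_c, alt_c,
                                     vaf, rna, tpm)
    raise RuntimeError("no synonymous site found")


def _design_fail_affinity(rng, t: TranscriptModel, spec: FixtureSpec,
                          predictor, vaf, rna, tpm,
                          spike: NeoSpike) -> SpikePlan:
    for _ in range(200):
        ridx = int(rng.integers(5, len(t.protein_sequence) - 5))
        codon = t.cds_sequence[3 * ridx : 3 * ridx + 3]
        off = int(rng.integers(3))
        nt = NT[int(rng.integers(4))]
        if nt == codon[off]:
            continue
        alt_codon = codon[:off] + nt + codon[off + 1:]
        if alt_codon in STOP_CODONS or \
                CODON_TABLE[alt_codon] == CODON_TABLE[codon]:
            continue
        i = 3 * ridx + off
        gpos = _cds_index_to_genomic(t.exon_intervals, t.strand,
                                     t.cds_length, i)
        ref_c, alt_c = t.cds_sequence[i], nt
        if t.strand == "-":
            ref_c, alt_c = reverse_complement(ref_c), reverse_complement(alt_c)
        plan = SpikePlan(spike, t.gene_id, t.transcript_id, t.chrom,
                         gpos + 1, ref_c, alt_c, vaf, rna, tpm)
        if _verify_spike(t, plan, spec, predictor):
            return plan
    raise RuntimeError("could not place a weak-binding missense spike")


def _check_reference(ref: Reference, predictor: SurrogatePredictor) -> None:
    """Construction-time verification of the designed properties."""
    consensus9 = predictor.consensus(ref.spec.class1_allele, 9)
    for t in ref.transcripts:
        if consensus9 in t.protein_sequence:
            raise RuntimeError(
                f"consensus peptide leaked into wild-type {t.transcript_id}")
    for plan in ref.spike_plans:
        t = ref.transcript(plan.transcript_id)
        if plan.spike.flag in ("pass", "fail:affinity", "synonymous"):
            if not _verify_spike(t, plan, ref.spec, predictor):
                raise RuntimeError(
                    f"spike {plan.spike.flag} on {plan.transcript_id} "
                    "does not behave as designed")


# ---------------------------------------------------------------------------
# serialization

def genome_fasta(ref: Reference, width: int = 70) -> str:
    out = []
    for chrom, seq in ref.genome.items():
        out.append(f">{chrom}")
        out.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


def annotation_gtf(ref: Reference) -> str:
    lines = []
    for t in ref.transcripts:
        attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                 f'gene_name "{t.gene_name}";')
        span = (t.exon_intervals[0][0] + 1, t.exon_intervals[-1][1])
        lines.append("\t".join([t.chrom, "synthetic", "transcript",
                                str(span[0]), str(span[1]), ".", t.strand,
                                ".", attrs]))
        ivs = (t.exon_intervals if t.strand == "+"
               else tuple(reversed(t.exon_intervals)))
        cum = 0
        for s, e in ivs:  # transcription order for frame bookkeeping
            frame = (3 - cum % 3) % 3
            lines.append("\t".join([t.chrom, "synthetic", "CDS",
                                    str(s + 1), str(e), ".", t.strand,
                                    str(frame), attrs]))
            cum += e - s
    return "\n".join(lines) + "\n"


def proteome_fasta(ref: Reference) -> str:
    return "".join(
        f">{t.transcript_id} {t.gene_id} {t.gene_name}\n{t.protein_sequence}\n"
        for t in ref.transcripts
    )


def spike_variants(ref: Reference) -> tuple[str, pd.DataFrame]:
    """Emit the spiked variants as VCF text plus the truth table.

    The truth table rows carry gene, transcript, variant id, the spike
    class, and the designed outcome flag; its "pass" rows are the exact
    expected neoantigen gene set.
    """
    plans = sorted(ref.spike_plans, key=lambda p: p.pos)
    header = "\n".join([
        "##fileformat=VCFv4.2",
        '##INFO=<ID=RNAD,Number=1,Type=Integer,'
        'Description="RNA-seq reads supporting the alt allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,'
        'Description="Tumor variant allele fraction">',
        f"##contig=<ID={next(iter(ref.genome))},"
        f"length={len(next(iter(ref.genome.values())))}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR",
    ])
    rows, records = [], []
    for p in plans:
        records.append("\t".join([
            p.chrom, str(p.pos), ".", p.ref, p.alt, ".", "PASS",
            f"RNAD={p.rna_alt_reads}", "GT:AF", f"0/1:{p.vaf:.4f}",
        ]))
        rows.append({
            "gene_id": p.gene_id,
            "transcript_id": p.transcript_id,
            "variant_id": f"{p.chrom}:{p.pos}:{p.ref}>{p.alt}",
            "variant_class": p.spike.variant_class,
            "expected": p.spike.flag,
        })
    vcf = header + "\n" + "\n".join(records) + "\n"
    return vcf, pd.DataFrame(rows)


def simulate_expression(
    ref: Reference,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Tumor-replicate and normal-panel transcript TPM matrices.

    Designated TAA transcripts exceed 1 TPM in tumor while their genes
    (isoform-summed) stay below 1 TPM in every normal tissue; decoys
    violate exactly one clause; neoantigen spike genes receive the
    tumor expression their truth flag requires. Background transcripts
    absorb the remaining mass so every sample sums to 1e6.
    """
    spec = ref.spec
    rng = np.random.default_rng(spec.seed + 1)
    tids = [t.transcript_id for t in ref.transcripts]
    gene_map = pd.Series({t.transcript_id: t.gene_id
                          for t in ref.transcripts})
    tumor_cols = [f"tumor_{i + 1}" for i in range(spec.n_tumor_replicates)]
    normal_cols = [f"normal_{i + 1}" for i in range(spec.n_normal_tissues)]

    tumor = pd.DataFrame(
        rng.lognormal(2.0, 1.0, size=(len(tids), len(tumor_cols))),
        index=tids, columns=tumor_cols)
    normal = pd.DataFrame(
        rng.lognormal(2.0, 1.0, size=(len(tids), len(normal_cols))),
        index=tids, columns=normal_cols)

    designed_t: dict[str, np.ndarray] = {}
    designed_n: dict[str, np.ndarray] = {}
    nt_, nn = len(tumor_cols), len(normal_cols)

    for plan in ref.spike_plans:
        # split designed gene TPM across the gene's isoforms
        for i, t in enumerate(ref.by_gene(plan.gene_id)):
            share = plan.tumor_gene_tpm / len(ref.by_gene(plan.gene_id))
            designed_t[t.transcript_id] = np.full(nt_, share)

    for tid in ref.taa_spike_transcripts:
        gid = gene_map[tid]
        designed_t[tid] = rng.uniform(5, 50, size=nt_)
        for t in ref.by_gene(gid):
            designed_n[t.transcript_id] = rng.uniform(
                0.0, 0.4 / len(ref.by_gene(gid)), size=nn)
            if t.transcript_id != tid:
                # isoform-specific overexpression: siblings stay < 1 TPM
                designed_t[t.transcript_id] = rng.uniform(0.05, 0.6, size=nt_)

    # decoy A: silent in normals but tumor TPM below threshold
    gid = gene_map[ref.taa_decoy_low_tumor]
    for t in ref.by_gene(gid):
        designed_t[t.transcript_id] = np.full(
            nt_, 0.8 if t.transcript_id == ref.taa_decoy_low_tumor else 0.3)
        designed_n[t.transcript_id] = rng.uniform(
            0.0, 0.3 / len(ref.by_gene(gid)), size=nn)

    # decoy B: tumor-high but the isoform SUM reaches 1.2 in one normal
    gid = gene_map[ref.taa_decoy_normal_sum]
    iso = ref.by_gene(gid)
    designed_t[ref.taa_decoy_normal_sum] = np.full(nt_, 2.0)
    hot = int(rng.integers(nn))
    for t in iso:
        vals = rng.uniform(0.0, 0.2 / len(iso), size=nn)
        vals[hot] = 1.2 / len(iso)  # each isoform < 1; the sum is 1.2
        designed_n[t.transcript_id] = vals

    def _assemble(base: pd.DataFrame, designed: dict) -> pd.DataFrame:
        out = base.copy()
        for tid, vals in designed.items():
            out.loc[tid] = vals
        design_mask = out.index.isin(designed)
        for col in out.columns:
            dsum = out.loc[design_mask, col].sum()
            bsum = out.loc[~design_mask, col].sum()
            out.loc[~design_mask, col] *= (TPM_TOTAL - dsum) / bsum
        return out

    tumor = _assemble(tumor, designed_t)
    normal = _assemble(normal, designed_n)
    return (
        ExpressionMatrix(tumor, gene_map, {c: "tumor" for c in tumor_cols}),
        ExpressionMatrix(normal, gene_map, {c: "normal" for c in normal_cols}),
    )


def simulate_enrichment(
    pre: pd.Series,
    target_genes: set[str],
    gene_map: pd.Series,
    e: float,
    o: float,
) -> pd.Series:
    """Noise-free capture: target-transcript TPM scaled by efficiency
    ``e``, off-target by ``o``, renormalized to a 1e6 pool."""
    if not (0 < o <= e <= 1):
        raise ValueError("require 0 < o <= e <= 1")
    on = gene_map.loc[pre.index].isin(target_genes).to_numpy()
    scaled = pre.to_numpy() * np.where(on, e, o)
    return pd.Series(scaled * (TPM_TOTAL / scaled.sum()), index=pre.index)


def expected_post_share(pre_target_tpm_sum: float, e: float,
                        o: float) -> float:
    """Closed-form post-capture target share (%) of a 1e6 TPM pool."""
    s = pre_target_tpm_sum
    return 100.0 * e * s / (e * s + o * (TPM_TOTAL - s))


def off_target_for_share(pre_target_tpm_sum: float, post_share_percent: float,
                         e: float = 1.0) -> float:
    """Invert the closed form: the off-target efficiency that turns a
    given pre-enrichment target mass into the requested post share."""
    s, p = pre_target_tpm_sum, post_share_percent
    return e * s * (100.0 - p) / (p * (TPM_TOTAL - s))


def expression_tsv(m: ExpressionMatrix) -> str:
    df = m.values.copy()
    df.insert(0, "gene_id", m.gene_map)
    df.index.name = "transcript_id"
    return df.to_csv(sep="\t", float_format="%.6f")


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize the full fixture bundle into a directory.

    Emits genome.fa, annotation.gtf, proteome.fa, variants.vcf,
    expression.tsv + samples.tsv (tumor replicates + normal panel),
    truth tables, the capture target list, and a pre/post enrichment
    expression pair.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = make_reference(spec)
    vcf, truth_neo = spike_variants(ref)
    tumor, normal = simulate_expression(ref)

    truth_taa = pd.DataFrame({
        "transcript_id": ref.taa_spike_transcripts,
        "gene_id": [tumor.gene_map[t] for t in ref.taa_spike_transcripts],
        "expected": "pass",
    })
    decoys = pd.DataFrame({
        "transcript_id": [ref.taa_decoy_low_tumor, ref.taa_decoy_normal_sum],
        "gene_id": [tumor.gene_map[ref.taa_decoy_low_tumor],
                    tumor.gene_map[ref.taa_decoy_normal_sum]],
        "expected": ["fail:tumor_tpm", "fail:normal_gene_tpm"],
    })
    truth_taa = pd.concat([truth_taa, decoys], ignore_index=True)

    pre = tumor.values[tumor.samples[0]]
    post = simulate_enrichment(pre, ref.tofu_target_genes, tumor.gene_map,
                               spec.capture_efficiency,
                               spec.off_target_efficiency)

    combined = pd.concat([tumor.values, normal.values], axis=1)
    combined_m = ExpressionMatrix(
        combined, tumor.gene_map,
        {**tumor.groups, **normal.groups})
    pre_m = ExpressionMatrix(pre.to_frame("pre"), tumor.gene_map,
                             {"pre": "tumor"})
    post_m = ExpressionMatrix(post.to_frame("post"), tumor.gene_map,
                              {"post": "tumor"})

    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "proteome": outdir / "proteome.fa",
        "vcf": outdir / "variants.vcf",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth_neoantigens": outdir / "truth_neoantigens.tsv",
        "truth_taas": outdir / "truth_taas.tsv",
        "targets": outdir / "targets.txt",
        "pre_enrichment": outdir / "pre_enrichment.tsv",
        "post_enrichment": outdir / "post_enrichment.tsv",
    }
    paths["genome"].write_text(genome_fasta(ref))
    paths["annotation"].write_text(annotation_gtf(ref))
    paths["proteome"].write_text(proteome_fasta(ref))
    paths["vcf"].write_text(vcf)
    paths["expression"].write_text(expression_tsv(combined_m))
    paths["samples"].write_text("".join(
        f"{s}\t{g}\n" for s, g in combined_m.groups.items()))
    truth_neo.to_csv(paths["truth_neoantigens"], sep="\t", index=False)
    truth_taa.to_csv(paths["truth_taas"], sep="\t", index=False)
    paths["targets"].write_text(
        "".join(f"{g}\n" for g in sorted(ref.tofu_target_genes)))
    paths["pre_enrichment"].write_text(expression_tsv(pre_m))
    paths["post_enrichment"].write_text(expression_tsv(post_m))
    return paths
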