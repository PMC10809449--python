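"""Neoantigen calling: somatic variant consequences and the stepwise
epitope filter chain.

Somatic SNVs and indels are applied to coding transcripts codon-aware
(frameshifts re-translate through the first new stop), mutant peptide
windows are enumerated (8-11-mers for MHC class I, 15-mers for class
II), and candidates are filtered stepwise: predicted binding affinity
(< 500 nM class I, < 1000 nM class II), variant allele fraction
(> 0.6), and gene expression (> 1 TPM). All inequalities are strict as
typeset; every rejection records the first failed step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .reference_model import TranscriptModel, reverse_complement, translate


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class Variant:
    """A somatic variant in VCF convention (1-based ``pos``; indels
    carry the anchor base in both alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    rna_alt_reads: int = 0
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.rna_alt_reads < 0:
            raise ValueError("rna_alt_reads must be non-negative")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref) == len(self.alt) == 1:
            return VariantClass.SNV
        if len(self.alt) > len(self.ref):
            return VariantClass.INSERTION
        if len(self.ref) > len(self.alt):
            return VariantClass.DELETION
        raise ValueError("multi-nucleotide substitutions are not supported")

    @property
    def is_frameshift(self) -> bool:
        return (len(self.alt) - len(self.ref)) % 3 != 0

    def short_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class VariantRejection(Exception):
    """Variant cannot yield a neoantigenic product on this transcript;
    ``reason`` is machine-readable."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class MutantProtein:
    """A transcript's mutant translation with the altered residue span.

    ``altered_range`` is 0-based half-open over mutant-protein indices:
    the residues differing from wild type, or (for frameshifts) the
    entire novel C-terminal tail. Empty range means a synonymous,
    non-antigenic outcome.
    """

    transcript_id: str
    gene_id: str
    wildtype_protein: str
    mutant_protein: str
    altered_range: tuple[int, int]
    consequence: str

    @property
    def is_antigenic(self) -> bool:
        return self.altered_range[0] < self.altered_range[1]


@dataclass(frozen=True)
class EpitopeCandidate:
    """A peptide window annotated for the filter chain. ``vaf`` is None
    for TAA-derived (non-mutated) epitopes, which skip the VAF step."""

    peptide: str
    mhc_class: str  # "I" or "II"
    allele: str
    gene_id: str
    transcript_id: str
    source: str  # "neoantigen" or "TAA"
    affinity_nm: float | None = None
    tumor_tpm: float | None = None
    vaf: float | None = None
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.mhc_class not in ("I", "II"):
            raise ValueError(f"mhc_class must be I or II, got {self.mhc_class!r}")
        if self.affinity_nm is not None and self.affinity_nm <= 0:
            raise ValueError("affinity_nm must be positive")


@dataclass(frozen=True)
class FilterThresholds:
    """The stepwise filter-chain cutoffs. All comparisons against
    max_*/min_* bounds are strict (boundary values fail)."""

    max_affinity_class1: float = 500.0
    max_affinity_class2: float = 1000.0
    min_vaf: float = 0.6
    min_tpm: float = 1.0
    min_rna_alt_reads: int = 1
    class1_lengths: tuple[int, ...] = (8, 9, 10, 11)
    class2_length: int = 15

    def __post_init__(self) -> None:
        if min(self.max_affinity_class1, self.max_affinity_class2,
               self.min_vaf, self.min_tpm) <= 0:
            raise ValueError("thresholds must be strictly positive")


def _cds_offset(t: TranscriptModel, genomic_pos0: int) -> int | None:
    """Offset of a genomic position within the plus-strand spliced CDS,
    or None if the position is not inside any CDS interval."""
    off = 0
    for s, e in t.exon_intervals:
        if s <= genomic_pos0 < e:
            return off + (genomic_pos0 - s)
        off += e - s
    return None


def _diff_range(wt: str, mut: str) -> tuple[int, int]:
    """Altered span on the mutant protein via common prefix/suffix
    trimming; guaranteed non-empty when the proteins differ."""
    if wt == mut:
        return (0, 0)
    p = 0
    while p < min(len(wt), len(mut)) and wt[p] == mut[p]:
        p += 1
    s = 0
    while (s < min(len(wt), len(mut)) - p
           and wt[len(wt) - 1 - s] == mut[len(mut) - 1 - s]):
        s += 1
    first, last = p, len(mut) - s
    if first >= last:
        # pure deletion: mark the junction residue
        first = max(0, min(first, len(mut) - 1))
        last = min(len(mut), first + 1)
    return (first, last)


def apply_variant(t: TranscriptModel, v: Variant) -> MutantProtein:
    """Apply a somatic variant to one transcript's CDS and translate.

    SNVs substitute a single codon; in-frame indels insert/delete
    residues; frameshift indels re-translate from the shifted frame
    through the first new stop (continuing into the 3' UTR when the
    transcript provides it). Synonymous outcomes return an empty
    ``altered_range``. Raises :class:`VariantRejection` for variants
    outside the CDS, stop-gains and start-losses (no novel peptide);
    raises ``ValueError`` if the ref allele mismatches the genome.
    """
    if v.chrom != t.chrom:
        raise VariantRejection("outside_cds", f"{v.short_id()} on other chromosome")
    pos0 = v.pos - 1
    off = _cds_offset(t, pos0)
    if off is None:
        raise VariantRejection("outside_cds",
                               f"{v.short_id()} not inside CDS of {t.transcript_id}")
    plus = t.plus_strand_spliced()
    if off + len(v.ref) > len(plus):
        raise VariantRejection("outside_cds",
                               f"{v.short_id()} ref allele extends past CDS end")
    observed = plus[off : off + len(v.ref)]
    if observed != v.ref.upper():
        raise ValueError(
            f"ref mismatch for {v.short_id()} on {t.transcript_id}: "
            f"genome has {observed!r}"
        )
    mut_plus = plus[:off] + v.alt.upper() + plus[off + len(v.ref):]
    mut_cds = mut_plus if t.strand == "+" else reverse_complement(mut_plus)

    wt = t.protein_sequence
    # frameshift / stop-loss products may run past the annotated stop
    mut = translate(mut_cds + t.utr3_sequence)

    if mut == wt:
        return MutantProtein(t.transcript_id, t.gene_id, wt, mut, (0, 0),
                             "synonymous")
    if not mut or mut[0] != "M":
        raise VariantRejection("start_loss",
                               f"{v.short_id()} disrupts the initiator codon")
    if len(mut) < len(wt) and wt.startswith(mut):
        raise VariantRejection("stop_gain",
                               f"{v.short_id()} truncates without novel sequence")

    if v.is_frameshift:
        first, _ = _diff_range(wt, mut)
        altered = (first, len(mut))
        consequence = "frameshift"
    else:
        altered = _diff_range(wt, mut)
        if len(mut) > len(wt) and mut.startswith(wt):
            # stop-loss read-through: novel tail after the old terminus
            altered = (len(wt), len(mut))
            consequence = "stop_loss"
        elif v.variant_class is VariantClass.SNV:
            consequence = "missense"
        else:
            consequence = "inframe_indel"
    return MutantProtein(t.transcript_id, t.gene_id, wt, mut, altered,
                         consequence)


def rna_expressed(v: Variant, thr: FilterThresholds) -> bool:
    """RNA-level confirmation: the variant has at least
    ``min_rna_alt_reads`` supporting RNA-seq reads (inclusive)."""
    return v.rna_alt_reads >= thr.min_rna_alt_reads


@dataclass(frozen=True)
class EpitopeWindow:
    peptide: str
    start: int  # 0-based offset in the mutant protein
    mhc_class: str


def enumerate_epitopes(
    m: MutantProtein, thr: FilterThresholds
) -> list[EpitopeWindow]:
    """All mutant peptide windows overlapping the altered residues.

    Class I windows at every length in ``class1_lengths``, class II at
    ``class2_length``; windows identical to a wild-type substring are
    removed (they cannot be neoantigens). Lengths exceeding the mutant
    protein contribute nothing.
    """
    lo, hi = m.altered_range
    if lo >= hi:
        raise ValueError("enumerate_epitopes requires a non-empty altered_range")
    prot = m.mutant_protein
    wt = m.wildtype_protein
    out: list[EpitopeWindow] = []
    for mhc_class, lengths in (("I", thr.class1_lengths),
                               ("II", (thr.class2_length,))):
        for k in lengths:
            if k > len(prot):
                continue
            # window [i, i+k) overlaps [lo, hi) iff i < hi and i+k > lo
            for i in range(max(0, lo - k + 1), min(hi, len(prot) - k + 1)):
                pep = prot[i : i + k]
                if pep in wt:
                    continue
                out.append(EpitopeWindow(pep, i, mhc_class))
    return out


#: filter-chain step order; rejections carry the first failed step
FILTER_STEPS = ("affinity", "VAF", "expression")


def select_neoantigens(
    candidates: list[EpitopeCandidate], thr: FilterThresholds
) -> tuple[list[EpitopeCandidate], dict[EpitopeCandidate, str]]:
    """Run the stepwise filter chain over epitope candidates.

    Retained iff affinity < class cutoff AND vaf > min_vaf AND
    tumor_tpm > min_tpm (strict; a candidate with ``vaf=None`` — a TAA
    epitope — skips the VAF step). Returns the retained list (stable
    input order, deduplicated on (peptide, allele, gene)) and a map of
    rejected candidate -> first failed step name.
    """
    retained: list[EpitopeCandidate] = []
    rejections: dict[EpitopeCandidate, str] = {}
    seen: set[tuple[str, str, str]] = set()
    for c in candidates:
        if c.affinity_nm is None:
            raise ValueError(
                f"candidate {c.peptide}/{c.allele} has no affinity; "
                "run the binding predictor first"
            )
        cutoff = (thr.max_affinity_class1 if c.mhc_class == "I"
                  else thr.max_affinity_class2)
        if not c.affinity_nm < cutoff:
            rejections[c] = "affinity"
            continue
        if c.vaf is not None and not c.vaf > thr.min_vaf:
            rejections[c] = "VAF"
            continue
        tpm = c.tumor_tpm if c.tumor_tpm is not None else 0.0
        if not tpm > thr.min_tpm:
            rejections[c] = "expression"
            continue
        key = (c.peptide, c.allele, c.gene_id)
        if key in seen:
            continue  # same peptide via another transcript of the gene
        seen.add(key)
        retained.append(c)
    return retained, rejections


def candidates_from_mutant(
    m: MutantProtein,
    windows: list[EpitopeWindow],
    *,
    alleles_class1: list[str],
    alleles_class2: list[str],
    predictor,
    tumor_tpm: float | None,
    vaf: float,
    variant_id: str,
) -> list[EpitopeCandidate]:
    """Score enumerated windows against every allele of the matching
    class, producing filter-ready candidates."""
    out = []
    for w in windows:
        alleles = alleles_class1 if w.mhc_class == "I" else alleles_class2
        for allele in alleles:
            out.append(EpitopeCandidate(
                peptide=w.peptide,
                mhc_class=w.mhc_class,
                allele=allele,
                gene_id=m.gene_id,
                transcript_id=m.transcript_id,
                source="neoantigen",
                affinity_nm=predictor.predict(w.peptide, allele),
                tumor_tpm=tumor_tpm,
                vaf=vaf,
                variant_id=variant_id,
            ))
    return out
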