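"""Reference sequence model: transcripts, translation, and a peptide index.

Loads a genome FASTA plus a Gencode-style GTF into
:class:`TranscriptModel` objects (spliced, strand-resolved CDS and
protein), and builds an exact-match k-mer index over the proteome used
by the peptide-uniqueness filter.

All internal coordinates are 0-based, half-open; 1-based inputs (GTF,
VCF) are converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
#: codon -> amino acid, standard genetic code
CODON_TABLE = dict(standard_dna_table.forward_table)


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript.

    ``exon_intervals`` are the genomic CDS pieces as (start, end) pairs,
    0-based half-open, sorted in genomic order. ``cds_sequence`` is the
    spliced, strand-resolved coding sequence beginning with ATG;
    ``protein_sequence`` is its translation up to (excluding) the first
    stop. ``utr3_sequence`` optionally carries spliced 3' UTR sequence so
    stop-loss and late frameshift variants can re-translate past the
    annotated stop.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exon_intervals: tuple[tuple[int, int], ...]
    cds_sequence: str
    protein_sequence: str
    utr3_sequence: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.cds_sequence) < 3:
            raise ValueError(
                f"{self.transcript_id}: CDS shorter than one codon"
            )
        ivs = self.exon_intervals
        for (s, e) in ivs:
            if not 0 <= s < e:
                raise ValueError(f"{self.transcript_id}: bad interval {(s, e)}")
        if any(ivs[i][1] > ivs[i + 1][0] for i in range(len(ivs) - 1)):
            raise ValueError(
                f"{self.transcript_id}: exon intervals overlap or are unsorted"
            )

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    def plus_strand_spliced(self) -> str:
        """Spliced CDS in genomic (plus-strand) orientation.

        For plus-strand transcripts this equals ``cds_sequence``; for
        minus-strand ones it is its reverse complement. Variant
        application edits in this space because VCF alleles are reported
        on the plus strand.
        """
        if self.strand == "+":
            return self.cds_sequence
        return str(Seq(self.cds_sequence).reverse_complement())


def translate(cds: str) -> str:
    """Translate a nucleotide sequence with the standard genetic code.

    Stops at the first in-frame stop codon (excluded from the output).
    Codons containing N translate to 'X'. A trailing partial codon is
    ignored. Raises ``ValueError`` on empty input or non-ACGTN letters.
    """
    if not cds:
        raise ValueError("cannot translate an empty sequence")
    seq = cds.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"unexpected letters in CDS: {bad}")
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            protein.append("X")
        elif codon in STOP_CODONS:
            break
        else:
            protein.append(CODON_TABLE[codon])
    return "".join(protein)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def load_transcripts(
    genome_fasta: str,
    annotation_gtf: str,
    *,
    require_atg: bool = True,
) -> list[TranscriptModel]:
    """Build :class:`TranscriptModel` objects from a genome and a GTF.

    CDS features are grouped by their ``transcript_id`` attribute,
    sorted in genomic order, extracted from the FASTA, spliced, and
    reverse-complemented for minus-strand transcripts. Transcripts whose
    CDS length is not a multiple of 3, or (by default) does not begin
    with ATG, are skipped with a warning; a CDS referencing a chromosome
    absent from the FASTA is a hard error naming the transcript.
    """
    import gffutils

    db = gffutils.create_db(
        annotation_gtf,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genome = Fasta(genome_fasta, as_raw=True, sequence_always_upper=True)

    groups: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.attributes["transcript_id"][0]
        groups.setdefault(tid, []).append(feat)

    models: list[TranscriptModel] = []
    for tid, feats in groups.items():
        feats.sort(key=lambda f: f.start)
        chrom = feats[0].seqid
        if chrom not in genome:
            raise ValueError(
                f"transcript {tid}: chromosome {chrom!r} missing from FASTA"
            )
        strand = feats[0].strand
        # GTF is 1-based inclusive -> 0-based half-open
        intervals = tuple((f.start - 1, f.end) for f in feats)
        plus_spliced = "".join(genome[chrom][s:e] for s, e in intervals)
        cds = plus_spliced if strand == "+" else reverse_complement(plus_spliced)
        if len(cds) % 3 != 0:
            logger.warning(
                "skipping %s: CDS length %d not divisible by 3", tid, len(cds)
            )
            continue
        if require_atg and not cds.startswith("ATG"):
            logger.warning("skipping %s: CDS does not begin with ATG", tid)
            continue
        protein = translate(cds)
        if not protein:
            logger.warning("skipping %s: empty translation", tid)
            continue
        attrs = feats[0].attributes
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=attrs.get("gene_id", [tid])[0],
                gene_name=attrs.get("gene_name", [""])[0],
                chrom=chrom,
                strand=strand,
                exon_intervals=intervals,
                cds_sequence=cds,
                protein_sequence=protein,
            )
        )
    return models


def load_proteome_fasta(path: str) -> list[TranscriptModel]:
    """Read a protein FASTA as a minimal set of transcript models.

    Headers are parsed as ``<transcript_id> [gene_id] [gene_name]``
    (whitespace-separated); missing fields fall back to the transcript
    id. Sequences gain a placeholder CDS so the models can feed the
    peptide index, which only reads protein sequences.
    """
    from Bio import SeqIO

    models = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.description.split()
        gene_id = parts[1] if len(parts) > 1 else rec.id
        gene_name = parts[2] if len(parts) > 2 else gene_id
        models.append(
            TranscriptModel(
                transcript_id=rec.id,
                gene_id=gene_id,
                gene_name=gene_name,
                chrom=".",
                strand="+",
                exon_intervals=((0, 3),),
                cds_sequence="ATG",
                protein_sequence=str(rec.seq).rstrip("*"),
            )
        )
    return models


@dataclass
class ProteomeIndex:
    """Exact-match lookup of every peptide of the proteome.

    Maps each length-k substring (min_len <= k <= max_len) of every
    indexed protein to the set of ``(gene_id, transcript_id)`` pairs
    whose protein contains it.
    """

    min_len: int
    max_len: int
    _index: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    transcript_ids: set[str] = field(default_factory=set)
    gene_ids: set[str] = field(default_factory=set)

    def query(self, peptide: str) -> set[tuple[str, str]]:
        """Return (gene_id, transcript_id) pairs whose protein contains
        ``peptide``; empty set if absent. Length must be in range."""
        if not self.min_len <= len(peptide) <= self.max_len:
            raise ValueError(
                f"peptide length {len(peptide)} outside indexed range "
                f"[{self.min_len}, {self.max_len}]"
            )
        return self._index.get(peptide, set())

    def __contains__(self, peptide: str) -> bool:
        return len(self.query(peptide)) > 0


def build_peptide_index(
    proteins: list[TranscriptModel], length_range: tuple[int, int]
) -> ProteomeIndex:
    """Index all constituent peptides of a proteome for exact lookup."""
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    if not proteins:
        raise ValueError("cannot index an empty proteome")
    idx = ProteomeIndex(min_len=lo, max_len=hi)
    for t in proteins:
        idx.transcript_ids.add(t.transcript_id)
        idx.gene_ids.add(t.gene_id)
        prot = t.protein_sequence
        key = (t.gene_id, t.transcript_id)
        for k in range(lo, hi + 1):
            for i in range(len(prot) - k + 1):
                idx._index.setdefault(prot[i : i + k], set()).add(key)
    return idx
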