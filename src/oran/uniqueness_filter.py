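"""Peptide-uniqueness screening against the reference proteome.

Guarantees tumor specificity of selected epitopes: a mutant
(neoantigen) epitope must not occur anywhere in the reference
proteome; a TAA epitope must not be shared with *expressed* isoforms
of other genes. Matching is exact — no mismatch tolerance — via the
:class:`~oran.reference_model.ProteomeIndex`; a fuzzy matcher can be
plugged in through the ``occurrences`` hook.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .neoantigen_caller import EpitopeCandidate
from .reference_model import ProteomeIndex

#: hook signature: peptide -> set of (gene_id, transcript_id) occurrences
OccurrenceFn = Callable[[str], set[tuple[str, str]]]


@dataclass
class ExpressedSet:
    """Transcripts considered expressed (transcript TPM above a
    threshold, default 1) in the relevant tissue context."""

    transcript_ids: set[str]
    tpm_threshold: float = 1.0

    @classmethod
    def from_matrix(cls, matrix, threshold: float = 1.0,
                    aggregation: str = "mean") -> "ExpressedSet":
        vals = (matrix.values.mean(axis=1) if aggregation == "mean"
                else matrix.values.max(axis=1))
        return cls(set(vals.index[vals > threshold]), threshold)


@dataclass
class UniquenessReport:
    retained: list[EpitopeCandidate]
    removed: list[EpitopeCandidate]
    #: candidate -> colliding (gene_id, transcript_id) pairs
    collisions: dict[EpitopeCandidate, set[tuple[str, str]]] = field(
        default_factory=dict)
    #: TAA-mode only: other-gene occurrences in non-expressed transcripts
    #: (reported, but not rejecting in default mode)
    silent_collisions: dict[EpitopeCandidate, set[tuple[str, str]]] = field(
        default_factory=dict)


def filter_unique_neoepitopes(
    candidates: list[EpitopeCandidate],
    idx: ProteomeIndex,
    occurrences: OccurrenceFn | None = None,
) -> UniquenessReport:
    """Retain mutant epitopes whose exact peptide string occurs nowhere
    in the reference proteome (its own wild type included)."""
    lookup = occurrences or idx.query
    report = UniquenessReport([], [])
    for c in candidates:
        hits = lookup(c.peptide)
        if hits:
            report.removed.append(c)
            report.collisions[c] = hits
        else:
            report.retained.append(c)
    return report


def filter_unique_taa_epitopes(
    candidates: list[EpitopeCandidate],
    idx: ProteomeIndex,
    expressed: ExpressedSet,
    *,
    strict: bool = False,
    occurrences: OccurrenceFn | None = None,
) -> UniquenessReport:
    """Retain TAA epitopes not shared by other expressed isoforms or
    genes.

    A candidate survives iff every *expressed* transcript containing
    its peptide belongs to the candidate's own gene. Occurrences in
    non-expressed transcripts of other genes are recorded in
    ``silent_collisions`` and, in default mode, do not reject;
    ``strict=True`` rejects on any other-gene occurrence regardless of
    expression.
    """
    lookup = occurrences or idx.query
    report = UniquenessReport([], [])
    for c in candidates:
        if c.gene_id not in idx.gene_ids:
            raise ValueError(
                f"candidate gene {c.gene_id} ({c.transcript_id}) absent "
                "from the proteome index"
            )
        hits = lookup(c.peptide)
        other = {(g, t) for g, t in hits if g != c.gene_id}
        blocking = other if strict else {
            (g, t) for g, t in other if t in expressed.transcript_ids
        }
        silent = other - blocking
        if silent:
            report.silent_collisions[c] = silent
        if blocking:
            report.removed.append(c)
            report.collisions[c] = blocking
        else:
            report.retained.append(c)
    return report


def rejection_table(report: UniquenessReport) -> list[dict]:
    """Rows for the rejection-report TSV: each removed epitope with its
    colliding gene/transcript ids."""
    rows = []
    for c in report.removed:
        for gid, tid in sorted(report.collisions.get(c, set())):
            rows.append({
                "peptide": c.peptide,
                "allele": c.allele,
                "source_gene": c.gene_id,
                "colliding_gene": gid,
                "colliding_transcript": tid,
            })
    return rows
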