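"""Hybrid-capture panel design and enrichment QC.

Designs tiling probes over selected antigen transcripts and validates
a captured (post-enrichment) library against its pre-enrichment pool:
the target set's TPM share of the pool before vs after capture, the
fold enrichment, and a per-gene volcano table of log2 fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference_model import TranscriptModel
from .taa_caller import ExpressionMatrix, gene_tpm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeDesignParams:
    """Tiling geometry: 120-nt probes every 60 nt by default, the
    common hybrid-capture half-overlap design."""

    probe_length: int = 120
    tiling_step: int = 60

    def __post_init__(self) -> None:
        if not 0 < self.tiling_step <= self.probe_length:
            raise ValueError("require 0 < tiling_step <= probe_length")


@dataclass(frozen=True)
class Probe:
    transcript_id: str
    start: int  # 0-based half-open on the transcript CDS
    end: int
    sequence: str
    short_flag: bool = False


def design_probes(t: TranscriptModel, p: ProbeDesignParams) -> list[Probe]:
    """Tile probes across a transcript so every base is covered.

    Probes start at 0, step, 2*step, ...; if the last regular probe does
    not reach the 3' end, a final probe is anchored to end exactly
    there. A transcript shorter than the probe length yields a single
    whole-transcript probe flagged short.
    """
    seq = t.cds_sequence
    n = len(seq)
    if n < p.probe_length:
        return [Probe(t.transcript_id, 0, n, seq, short_flag=True)]
    starts = list(range(0, n - p.probe_length + 1, p.tiling_step))
    if starts[-1] + p.probe_length < n:
        starts.append(n - p.probe_length)
    return [
        Probe(t.transcript_id, s, s + p.probe_length,
              seq[s : s + p.probe_length])
        for s in starts
    ]


def percent_of_pool(sample: pd.Series, targets: set[str],
                    gene_map: pd.Series | None = None) -> float:
    """Share (%) of an expression pool held by the target gene set.

    ``sample`` is a TPM vector indexed by transcript_id (or gene_id if
    ``gene_map`` is None and the index already is gene-level); TPM
    weighting makes the share an abundance fraction, invariant under
    uniform rescaling of the vector.
    """
    total = float(sample.sum())
    if total <= 0:
        raise ValueError("expression pool is empty")
    ids = sample.index if gene_map is None else gene_map.loc[sample.index]
    on_target = float(sample[np.asarray([i in targets for i in ids])].sum())
    return 100.0 * on_target / total


def fold_enrichment(pre_percent: float, post_percent: float) -> float:
    """post/pre pool-share ratio; pre = 0 reports infinity with a
    warning rather than failing."""
    if pre_percent < 0 or post_percent < 0:
        raise ValueError("percentages must be non-negative")
    if pre_percent == 0:
        logger.warning("pre-enrichment share is 0%%; fold is infinite")
        return math.inf
    return post_percent / pre_percent


def per_gene_enrichment(
    pre: pd.DataFrame | pd.Series,
    post: pd.DataFrame | pd.Series,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene volcano table: log2((post+pc)/(pre+pc)).

    Accepts single samples (Series) or replicate matrices (DataFrame,
    genes x replicates). With replicates on both sides an unpaired
    two-sample t-statistic on log-TPM and a Benjamini-Hochberg adjusted
    p-value are added per gene.
    """
    pre_df = pre.to_frame() if isinstance(pre, pd.Series) else pre
    post_df = post.to_frame() if isinstance(post, pd.Series) else post
    genes = pre_df.index.intersection(post_df.index)
    pre_df, post_df = pre_df.loc[genes], post_df.loc[genes]

    pre_mean = pre_df.mean(axis=1)
    post_mean = post_df.mean(axis=1)
    out = pd.DataFrame({
        "pre_tpm": pre_mean,
        "post_tpm": post_mean,
        "log2_fold_change": np.log2((post_mean + pseudocount)
                                    / (pre_mean + pseudocount)),
    })
    if pre_df.shape[1] > 1 and post_df.shape[1] > 1:
        lp = np.log2(pre_df + pseudocount)
        lq = np.log2(post_df + pseudocount)
        tstat, pval = stats.ttest_ind(lq, lp, axis=1)
        from statsmodels.stats.multitest import multipletests

        pval = np.nan_to_num(pval, nan=1.0)
        out["t_statistic"] = tstat
        out["p_value"] = pval
        out["p_adjusted"] = multipletests(pval, method="fdr_bh")[1]
    return out


@dataclass
class EnrichmentReport:
    """Pre- vs post-capture QC of a panel against its target genes."""

    target_gene_set: set[str]
    pre_percent: float
    post_percent: float
    fold_enrichment: float
    per_gene: pd.DataFrame

    def __post_init__(self) -> None:
        assert 0 <= self.pre_percent <= 100
        assert 0 <= self.post_percent <= 100


def enrichment_qc(
    pre: ExpressionMatrix,
    post: ExpressionMatrix,
    targets: set[str],
    pseudocount: float = 0.01,
) -> EnrichmentReport:
    """Full QC: pool shares, fold, and the per-gene volcano table, all
    at gene level (isoform-summed)."""
    pre_gene = gene_tpm(pre)
    post_gene = gene_tpm(post)
    known = targets & set(pre_gene.index)
    unknown = targets - known
    if unknown:
        logger.warning("ignoring %d target genes absent from the pool: %s",
                       len(unknown), sorted(unknown)[:5])
    pre_pct = float(np.mean([percent_of_pool(pre_gene[c], known)
                             for c in pre_gene.columns]))
    post_pct = float(np.mean([percent_of_pool(post_gene[c], known)
                              for c in post_gene.columns]))
    return EnrichmentReport(
        target_gene_set=known,
        pre_percent=pre_pct,
        post_percent=post_pct,
        fold_enrichment=fold_enrichment(pre_pct, post_pct),
        per_gene=per_gene_enrichment(pre_gene, post_gene, pseudocount),
    )


def probes_to_fasta(probes: list[Probe]) -> str:
    recs = []
    for i, p in enumerate(probes, 1):
        recs.append(f">{p.transcript_id}|probe{i}|{p.start}-{p.end}"
                    f"{'|short' if p.short_flag else ''}\n{p.sequence}")
    return "\n".join(recs) + "\n"


def probes_to_bed(probes: list[Probe]) -> str:
    lines = ["\t".join((p.transcript_id, str(p.start), str(p.end)))
             for p in probes]
    return "\n".join(lines) + "\n"
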