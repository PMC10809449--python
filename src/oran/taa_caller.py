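"""Tumor-associated antigen (TAA) calling from expression matrices.

A transcript is a TAA when its tumor expression exceeds 1 TPM while its
*gene* (sum over all isoforms) stays below 1 TPM in every tissue of a
normal panel. Gene TPM is the isoform sum so that an isoform silent in
normals cannot be called when sibling isoforms of the same gene are
expressed there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Transcript-level TPM per sample.

    ``values``: DataFrame indexed by transcript_id, one column per
    sample. ``gene_map``: Series transcript_id -> gene_id (every
    transcript maps to exactly one gene). ``groups``: sample_id ->
    {"tumor", "normal"}; may be empty when the matrix holds one group.
    """

    values: pd.DataFrame
    gene_map: pd.Series
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = self.values.index.difference(self.gene_map.index)
        if len(missing):
            raise ValueError(
                f"transcripts without a gene mapping: {list(missing[:5])}"
            )
        self.gene_map = self.gene_map.loc[self.values.index]
        totals = self.values.sum(axis=0)
        off = totals[(totals - TPM_TOTAL).abs() > 0.01 * TPM_TOTAL]
        if len(off):
            warnings.warn(
                "per-sample TPM totals deviate >1% from 1e6 for samples "
                f"{list(off.index[:5])}; values may not be proper TPM",
                stacklevel=2,
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, group: str) -> "ExpressionMatrix":
        cols = [s for s in self.samples if self.groups.get(s) == group]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ExpressionMatrix(self.values[cols], self.gene_map,
                                    {c: group for c in cols})


def load_expression_tsv(
    expression_path: str | Path, groups_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a TSV with columns transcript_id, gene_id, then one column
    per sample; optionally a two-column (sample_id, group) file."""
    df = pd.read_csv(expression_path, sep="\t")
    if list(df.columns[:2]) != ["transcript_id", "gene_id"]:
        raise ValueError(
            f"{expression_path}: first two columns must be transcript_id, "
            f"gene_id; got {list(df.columns[:2])}"
        )
    df = df.set_index("transcript_id")
    gene_map = df["gene_id"]
    values = df.drop(columns="gene_id").astype(float)
    groups: dict[str, str] = {}
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t", header=None,
                          names=["sample_id", "group"], comment="#")
        groups = dict(zip(gdf["sample_id"], gdf["group"]))
    return ExpressionMatrix(values, gene_map, groups)


def gene_tpm(m: ExpressionMatrix) -> pd.DataFrame:
    """Gene-level TPM per sample: the sum of isoform TPM of each gene."""
    return m.values.groupby(m.gene_map).sum()


@dataclass(frozen=True)
class TaaCall:
    transcript_id: str
    gene_id: str
    tumor_tpm: float
    max_normal_gene_tpm: float
    passed: bool
    replicate_pass_pattern: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.passed:
            assert self.tumor_tpm > 1 and self.max_normal_gene_tpm < 1


def call_taas(
    tumor: ExpressionMatrix,
    normals: ExpressionMatrix,
    *,
    tumor_tpm_threshold: float = 1.0,
    normal_gene_tpm_threshold: float = 1.0,
    aggregation: str = "mean",
) -> list[TaaCall]:
    """Apply the dual transcript/gene TPM rule against a normal panel.

    A transcript is called iff its aggregated tumor TPM exceeds
    ``tumor_tpm_threshold`` (strict >) AND its gene's isoform-summed
    TPM stays below ``normal_gene_tpm_threshold`` (strict <) in *every*
    normal sample. ``aggregation`` over tumor replicates is "mean"
    (default) or "union" (max: any replicate above threshold
    qualifies); the per-replicate pass pattern is reported either way.
    """
    if not normals.samples:
        raise ValueError("normal panel is empty")
    if aggregation not in ("mean", "union"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    shared = tumor.values.index.intersection(normals.values.index)
    if not len(shared):
        raise ValueError("tumor and normal matrices share no transcripts")

    normal_gene = gene_tpm(normals)  # genes x normal samples
    max_normal_gene = normal_gene.max(axis=1)

    tvals = tumor.values.loc[shared]
    agg = tvals.mean(axis=1) if aggregation == "mean" else tvals.max(axis=1)

    calls = []
    for tid in shared:
        gid = tumor.gene_map[tid]
        mng = float(max_normal_gene.get(gid, 0.0))
        tumor_val = float(agg[tid])
        passed = tumor_val > tumor_tpm_threshold and mng < normal_gene_tpm_threshold
        calls.append(TaaCall(
            transcript_id=tid,
            gene_id=gid,
            tumor_tpm=tumor_val,
            max_normal_gene_tpm=mng,
            passed=passed,
            replicate_pass_pattern=tuple(
                bool(v > tumor_tpm_threshold) for v in tvals.loc[tid]
            ),
        ))
    return calls


def calls_to_frame(calls: list[TaaCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "transcript_id": c.transcript_id,
        "gene_id": c.gene_id,
        "tumor_tpm": c.tumor_tpm,
        "max_normal_gene_tpm": c.max_normal_gene_tpm,
        "passed": c.passed,
        "replicate_pass_pattern": "".join("1" if p else "0"
                                          for p in c.replicate_pass_pattern),
    } for c in calls])
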