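"""Immune-monitoring statistics: ELISA reactivity calls, TCR clone-size
binning, Chao1 richness, and Vbeta-family composition.

Clone tables follow the MiXCR export convention (one row per
clonotype with read counts and V-gene hits); frequencies are read
shares of the repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ReactivityRule:
    """An antigen is reactive when IFN-gamma exceeds ``min_ifng``
    (strict, pg/ml) AND is at least ``min_fold_over_irrelevant`` times
    the irrelevant-peptide response (inclusive)."""

    min_ifng: float = 100.0
    min_fold_over_irrelevant: float = 2.0

    def __post_init__(self) -> None:
        if self.min_ifng <= 0 or self.min_fold_over_irrelevant <= 0:
            raise ValueError("rule thresholds must be positive")


def classify_reactivity(
    target_ifng: float,
    irrelevant_ifng: float,
    rule: ReactivityRule = ReactivityRule(),
) -> bool:
    if target_ifng < 0 or irrelevant_ifng < 0:
        raise ValueError("IFN-gamma concentrations must be non-negative")
    return (target_ifng > rule.min_ifng
            and target_ifng >= rule.min_fold_over_irrelevant * irrelevant_ifng)


@dataclass(frozen=True)
class Clone:
    clone_id: str
    cdr3: str
    vb_family: str
    read_count: int


@dataclass
class CloneTable:
    clones: list[Clone]

    def __post_init__(self) -> None:
        if any(c.read_count < 1 for c in self.clones):
            raise ValueError("read_count must be >= 1 for every clone")

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clones)

    def frequencies(self) -> dict[str, float]:
        total = self.total_reads
        if total == 0:
            raise ValueError("clone table has zero total reads")
        return {c.clone_id: c.read_count / total for c in self.clones}


def trim_v_hit(v_hits: str) -> str:
    """Reduce a MiXCR ``allVHitsWithScore``-style string to its V
    family (e.g. ``"TRBV13-1*00(1200)"`` -> ``"TRBV13"``); empty input
    maps to ``"unassigned"``."""
    if not v_hits or not v_hits.strip():
        return "unassigned"
    first = v_hits.split(",")[0].strip()
    name = first.split("*")[0].split("(")[0]
    name = name.split("-")[0]
    return name or "unassigned"


def load_clone_tsv(path) -> CloneTable:
    """Read a clone TSV with columns clone_id, cdr3, vb_family,
    read_count; vb_family accepts MiXCR V-hit strings (trimmed to the
    family)."""
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "cdr3", "vb_family", "read_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    clones = [
        Clone(str(r.clone_id), str(r.cdr3),
              trim_v_hit("" if pd.isna(r.vb_family) else str(r.vb_family)),
              int(r.read_count))
        for r in df.itertuples()
    ]
    return CloneTable(clones)


@dataclass(frozen=True)
class CloneBinSchema:
    """Clone-size bins as read-share thresholds, inclusive at each
    boundary: hyperexpanded >= 1%, large >= 0.1%, medium >= 0.01%,
    small >= 0.001%, rare below."""

    thresholds: tuple[tuple[str, float], ...] = (
        ("hyperexpanded", 0.01),
        ("large", 0.001),
        ("medium", 0.0001),
        ("small", 0.00001),
    )
    rare_label: str = "rare"

    def __post_init__(self) -> None:
        vals = [v for _, v in self.thresholds]
        if any(a <= b for a, b in zip(vals, vals[1:])):
            raise ValueError("bin thresholds must be strictly decreasing")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.thresholds) + (self.rare_label,)

    def bin_of(self, frequency: float) -> str:
        for name, thr in self.thresholds:
            if frequency >= thr:
                return name
        return self.rare_label


def bin_clones(
    t: CloneTable, schema: CloneBinSchema = CloneBinSchema()
) -> tuple[dict[str, str], dict[str, float]]:
    """Assign each clone its size bin and summarize read share per bin.

    Returns (clone_id -> bin label, bin label -> fraction of total
    reads); the summary covers every bin label and sums to 1.
    """
    if not t.clones:
        raise ValueError("clone table is empty")
    freqs = t.frequencies()
    labels = {cid: schema.bin_of(f) for cid, f in freqs.items()}
    shares = {name: 0.0 for name in schema.labels}
    for c in t.clones:
        shares[labels[c.clone_id]] += freqs[c.clone_id]
    return labels, shares


def chao_richness(t: CloneTable) -> float:
    """Bias-corrected Chao1 richness:
    S_obs + f1*(f1-1) / (2*(f2+1)), where f1/f2 are the singleton and
    doubleton clone counts. Always >= S_obs; equals it when f1 = 0."""
    if not t.clones:
        raise ValueError("clone table is empty")
    s_obs = len(t.clones)
    f1 = sum(1 for c in t.clones if c.read_count == 1)
    f2 = sum(1 for c in t.clones if c.read_count == 2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def chao_group_mean(tables: list[CloneTable]) -> float:
    """Mean of per-sample Chao1 estimates over a treatment group."""
    if not tables:
        raise ValueError("no clone tables supplied")
    return sum(chao_richness(t) for t in tables) / len(tables)


def vb_distribution(t: CloneTable) -> dict[str, float]:
    """Read share per Vbeta family (empty labels grouped under
    "unassigned"); shares sum to 1."""
    total = t.total_reads
    if total == 0:
        raise ValueError("clone table has zero total reads")
    shares: dict[str, float] = {}
    for c in t.clones:
        fam = c.vb_family or "unassigned"
        shares[fam] = shares.get(fam, 0.0) + c.read_count / total
    return shares
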