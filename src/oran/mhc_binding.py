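"""pMHC binding-affinity prediction contract and adapters.

External predictors (the NetMHC family, pVACtools output) are
integrated only through a TSV adapter; for self-contained testing the
module ships a deterministic surrogate scorer built on per-allele
position weight matrices. Affinities are IC50-like, in nM, lower =
stronger, on the conventional 1-50000 nM scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Protocol, runtime_checkable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MIN_NM = 1.0
MAX_NM = 50000.0


@runtime_checkable
class AffinityPredictor(Protocol):
    """Contract: deterministic (peptide, allele) -> affinity in nM."""

    supported_alleles: tuple[str, ...]

    def predict(self, peptide: str, allele: str) -> float: ...


@dataclass(frozen=True)
class SurrogatePwm:
    """Per-position amino-acid score matrix for one (allele, length).

    ``scores[i][aa]`` is the contribution of amino acid ``aa`` at
    position ``i``. The calibration mapping raw score to nM is monotone
    decreasing, so the per-position argmax (consensus) peptide attains
    the minimum nM over all peptides of the length.
    """

    allele: str
    length: int
    scores: tuple[dict[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.scores) != self.length:
            raise ValueError("matrix width does not match peptide length")

    @property
    def max_score(self) -> float:
        return sum(max(col.values()) for col in self.scores)

    def consensus(self) -> str:
        return "".join(max(col, key=col.get) for col in self.scores)

    def raw_score(self, peptide: str) -> float:
        return sum(col[aa] for col, aa in zip(self.scores, peptide))


def calibrate(raw: float, max_score: float) -> float:
    """Map a raw PWM score onto the 1-50000 nM scale.

    nM = 50000^(1 - s/s_max), clipped to [1, 50000]: the consensus
    score maps to 1 nM and the mapping is strictly decreasing in s.
    """
    nm = MAX_NM ** (1.0 - raw / max_score)
    return min(max(nm, MIN_NM), MAX_NM)


def _parse_pwm(text: str) -> SurrogatePwm:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header: dict[str, str] = {}
    rows: list[list[str]] = []
    for ln in lines:
        fields = ln.split()
        if fields[0] in ("allele", "length"):
            header[fields[0]] = fields[1]
        elif fields[0] != "aa":
            rows.append(fields)
    length = int(header["length"])
    cols: list[dict[str, float]] = [{} for _ in range(length)]
    for row in rows:
        aa, values = row[0], [float(v) for v in row[1:]]
        if len(values) != length:
            raise ValueError(f"PWM row {aa!r} has {len(values)} values, expected {length}")
        for i, v in enumerate(values):
            cols[i][aa] = v
    for i, col in enumerate(cols):
        if set(col) != set(AMINO_ACIDS):
            raise ValueError(f"PWM column {i} does not cover the 20 amino acids")
    return SurrogatePwm(allele=header["allele"], length=length, scores=tuple(cols))


def load_pwm_file(path: str | Path) -> SurrogatePwm:
    return _parse_pwm(Path(path).read_text())


def packaged_pwms() -> list[SurrogatePwm]:
    """Load the toy matrices shipped with the package (toy-Kb at
    lengths 8-11 for class I, toy-IAb at 15 for class II)."""
    pwms = []
    root = resources.files("oran").joinpath("data/pwm")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".pwm"):
            pwms.append(_parse_pwm(entry.read_text()))
    return pwms


class SurrogatePredictor:
    """Deterministic PWM-backed affinity predictor for testing.

    One matrix per (allele, peptide length); unknown allele or a length
    without a matrix is an error.
    """

    def __init__(self, pwms: list[SurrogatePwm] | None = None):
        self._pwms: dict[tuple[str, int], SurrogatePwm] = {}
        for pwm in pwms if pwms is not None else packaged_pwms():
            self._pwms[(pwm.allele, pwm.length)] = pwm
        self.supported_alleles = tuple(
            sorted({allele for allele, _ in self._pwms})
        )

    def matrix(self, allele: str, length: int) -> SurrogatePwm:
        if allele not in self.supported_alleles:
            raise KeyError(f"unknown allele {allele!r}; have {self.supported_alleles}")
        try:
            return self._pwms[(allele, length)]
        except KeyError:
            raise KeyError(
                f"allele {allele!r} has no matrix for peptide length {length}"
            ) from None

    def predict(self, peptide: str, allele: str) -> float:
        pwm = self.matrix(allele, len(peptide))
        if set(peptide) - set(AMINO_ACIDS):
            raise ValueError(f"non-standard residues in peptide {peptide!r}")
        return calibrate(pwm.raw_score(peptide), pwm.max_score)

    def consensus(self, allele: str, length: int) -> str:
        return self.matrix(allele, length).consensus()


class TablePredictor:
    """Affinity predictor backed by an externally computed table."""

    def __init__(self, table: dict[tuple[str, str], float], source: str = "<table>"):
        self._table = dict(table)
        self.source = source
        self.supported_alleles = tuple(sorted({a for _, a in table}))

    def predict(self, peptide: str, allele: str) -> float:
        try:
            return self._table[(peptide, allele)]
        except KeyError:
            raise KeyError(
                f"no affinity for (peptide={peptide!r}, allele={allele!r}) "
                f"in {self.source}"
            ) from None

    def missing_keys(self, queries: list[tuple[str, str]]) -> list[tuple[str, str]]:
        return [q for q in queries if q not in self._table]


def load_external_affinities(path: str | Path) -> TablePredictor:
    """Parse a TSV of externally computed affinities.

    Columns: peptide, allele, affinity_nm. Malformed rows and duplicate
    (peptide, allele) keys with conflicting values are errors naming the
    line number.
    """
    table: dict[tuple[str, str], float] = {}
    lineno_of: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["peptide", "allele", "affinity_nm"]
        if header[:3] != required:
            raise ValueError(
                f"{path}: expected header columns {required}, got {header[:3]}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            peptide, allele = fields[0], fields[1]
            try:
                nm = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: affinity_nm {fields[2]!r} is not a number"
                ) from None
            if not (0 < nm <= MAX_NM) or math.isnan(nm):
                raise ValueError(
                    f"{path}:{lineno}: affinity {nm} outside (0, {MAX_NM}]"
                )
            key = (peptide, allele)
            if key in table and table[key] != nm:
                raise ValueError(
                    f"{path}:{lineno}: duplicate entry for {key} conflicts "
                    f"with line {lineno_of[key]} ({table[key]} vs {nm})"
                )
            table[key] = nm
            lineno_of[key] = lineno
    return TablePredictor(table, source=str(path))
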