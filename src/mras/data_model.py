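"""Domain types and I/O for the disease-target-ncRNA tripartite network.

A tripartite network couples three disjoint node classes — diseases,
targets (the bridging biomolecules: genes, proteins, microRNAs) and
non-coding RNAs — through two bipartite edge sets: disease-target
(``A_DT``, shape m x n) and target-ncRNA (``A_TR``, shape n x p).
Sequences are attached to targets and ncRNAs as :class:`SequenceRecord`
objects; diseases carry no sequence.

Interaction tables are two-column TSV edge lists; sequences are FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

TARGET = "target"
NCRNA = "ncrna"
_ENTITY_CLASSES = (TARGET, NCRNA)


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (target protein/gene or ncRNA nucleotide string).

    The sequence is upper-cased on construction; no alphabet is enforced
    because targets are typically protein and ncRNAs nucleotide, and the
    downstream l-gram features use whatever characters appear.
    """

    id: str
    sequence: str
    entity_class: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has an empty identifier")
        if self.entity_class not in _ENTITY_CLASSES:
            raise ValueError(
                f"entity_class must be one of {_ENTITY_CLASSES}, got {self.entity_class!r}"
            )
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


def _check_binary(a: np.ndarray, name: str) -> None:
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be a binary matrix")


@dataclass
class TripartiteNetwork:
    """Ordered node lists plus the two binary bipartite adjacency matrices.

    Matrix rows/columns are indexed by the order of the identifier lists:
    ``A_DT[i, j] = 1`` iff disease ``diseases[i]`` interacts with target
    ``targets[j]``, and ``A_TR[j, k] = 1`` iff target ``targets[j]``
    interacts with ncRNA ``ncrnas[k]``.
    """

    diseases: list[str]
    targets: list[str]
    ncrnas: list[str]
    A_DT: np.ndarray
    A_TR: np.ndarray

    def __post_init__(self) -> None:
        self.diseases = list(self.diseases)
        self.targets = list(self.targets)
        self.ncrnas = list(self.ncrnas)
        _check_unique(self.diseases, "disease")
        _check_unique(self.targets, "target")
        _check_unique(self.ncrnas, "ncRNA")
        self.A_DT = np.asarray(self.A_DT, dtype=float)
        self.A_TR = np.asarray(self.A_TR, dtype=float)
        if self.A_DT.shape != (len(self.diseases), len(self.targets)):
            raise ValueError(
                f"A_DT shape {self.A_DT.shape} does not match "
                f"({len(self.diseases)}, {len(self.targets)})"
            )
        if self.A_TR.shape != (len(self.targets), len(self.ncrnas)):
            raise ValueError(
                f"A_TR shape {self.A_TR.shape} does not match "
                f"({len(self.targets)}, {len(self.ncrnas)})"
            )
        _check_binary(self.A_DT, "A_DT")
        _check_binary(self.A_TR, "A_TR")

    @property
    def m(self) -> int:
        return len(self.diseases)

    @property
    def n(self) -> int:
        return len(self.targets)

    @property
    def p(self) -> int:
        return len(self.ncrnas)

    def copy(self) -> "TripartiteNetwork":
        return TripartiteNetwork(
            list(self.diseases),
            list(self.targets),
            list(self.ncrnas),
            self.A_DT.copy(),
            self.A_TR.copy(),
        )


@dataclass
class DegreeSummary:
    """Node/edge counts and the cumulative degree distribution.

    ``cumulative_distribution`` lists ``(k, fraction of nodes with
    degree >= k)`` for k = 0 .. max degree; it is non-increasing and
    starts at exactly 1.
    """

    node_count: int
    edge_count: int
    average_degree: float
    cumulative_distribution: list[tuple[int, float]] = field(default_factory=list)


def read_fasta(path: str | Path, entity_class: str) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The identifier is the header token before the first whitespace;
    wrapped sequence lines are concatenated and upper-cased.

    Raises ``ValueError`` on an empty file, a duplicate identifier, or
    an entry with no sequence.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA identifier: {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq)
        if not seq:
            raise ValueError(f"empty sequence for {entry.id!r} in {path}")
        records.append(SequenceRecord(entry.id, seq, entity_class))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start : start + width] + "\n")


def read_interactions(
    path: str | Path,
    left_ids: Sequence[str],
    right_ids: Sequence[str],
) -> np.ndarray:
    """Read a two-column TSV edge list into a binary |left| x |right| matrix.

    Repeated edges collapse to a single 1.  A header line is tolerated:
    if the first line's tokens are not both known identifiers it is
    skipped; on any later line an unknown identifier raises ``ValueError``
    naming it.
    """
    left_index = {i: k for k, i in enumerate(left_ids)}
    right_index = {i: k for k, i in enumerate(right_ids)}
    mat = np.zeros((len(left_ids), len(right_ids)), dtype=float)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            left, right = parts[0].strip(), parts[1].strip()
            if left not in left_index or right not in right_index:
                if lineno == 1:
                    continue  # header line
                missing = left if left not in left_index else right
                raise ValueError(f"{path}:{lineno}: unknown identifier {missing!r}")
            mat[left_index[left], right_index[right]] = 1.0
    return mat


def write_interactions(
    matrix: np.ndarray,
    left_ids: Sequence[str],
    right_ids: Sequence[str],
    path: str | Path,
    header: tuple[str, str] | None = None,
) -> None:
    """Write the 1-entries of a binary matrix as a two-column TSV edge list."""
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        if header is not None:
            fh.write(f"{header[0]}\t{header[1]}\n")
        rows, cols = np.nonzero(matrix)
        for r, c in zip(rows, cols):
            fh.write(f"{left_ids[r]}\t{right_ids[c]}\n")


def node_degrees(net: TripartiteNetwork) -> np.ndarray:
    """Per-node degree vector over all m+n+p nodes (diseases, targets, ncRNAs).

    A target's degree counts edges in both layers: its column sum in
    ``A_DT`` plus its row sum in ``A_TR``.
    """
    deg_d = net.A_DT.sum(axis=1)
    deg_t = net.A_DT.sum(axis=0) + net.A_TR.sum(axis=1)
    deg_r = net.A_TR.sum(axis=0)
    return np.concatenate([deg_d, deg_t, deg_r])


def degree_summary(net: TripartiteNetwork) -> DegreeSummary:
    """Summarise the network: V, E, average degree 2E/V, cumulative distribution."""
    v = net.m + net.n + net.p
    if v == 0:
        raise ValueError("empty network: no nodes")
    degrees = node_degrees(net)
    e = int(net.A_DT.sum() + net.A_TR.sum())
    avg = 2.0 * e / v
    max_deg = int(degrees.max()) if v else 0
    cumulative = [
        (k, float(np.mean(degrees >= k))) for k in range(0, max_deg + 1)
    ]
    return DegreeSummary(v, e, avg, cumulative)


def degree_summary_frame(summary: DegreeSummary) -> pd.DataFrame:
    """Cumulative degree distribution as a DataFrame (for TSV export/plotting)."""
    return pd.DataFrame(
        summary.cumulative_distribution, columns=["degree", "fraction_ge"]
    )
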