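"""Minimum-entropy decomposition of aligned amplicons into oligotypes.

Aligned, equal-length reads are partitioned recursively: at each node the
Shannon entropy of every alignment column (gaps counted as a fifth state,
multiplicity-weighted) is computed, and if the maximum exceeds a small
floor the reads are split by their residue at that single column.  Terminal
nodes must reach a minimum substantive abundance ``M`` — the count of the
node's most abundant unique sequence — or their reads are dissolved into
the outlier pool; within surviving nodes, reads further than
``max_variation`` mismatches from the node representative are also set
aside as outliers.  This resolves taxa down to single-nucleotide
differences, finer than conventional 97%-identity OTUs.

Only single-position decomposition (``d=1``) is supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT-"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_SIZE_RE = re.compile(r";size=(\d+)")


class UnsupportedParameterError(ValueError):
    """Raised for decomposition parameters outside the supported range."""


@dataclass
class AlignedReadSet:
    """Equal-length aligned reads over {A,C,G,T,-} with multiplicities."""

    sequences: list
    multiplicities: np.ndarray

    def __post_init__(self):
        self.multiplicities = np.asarray(self.multiplicities, dtype=np.int64)
        if len(self.sequences) == 0:
            raise ValueError("empty read set")
        if len(self.sequences) != len(self.multiplicities):
            raise ValueError("one multiplicity per sequence required")
        if (self.multiplicities < 1).any():
            raise ValueError("multiplicities must be >= 1")
        L = len(self.sequences[0])
        for s in self.sequences:
            if len(s) != L:
                raise ValueError("reads must all have the same length")
            if any(c not in _CODE for c in s):
                raise ValueError(f"invalid residue in read: {s!r}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def total_reads(self) -> int:
        return int(self.multiplicities.sum())

    def unique(self) -> tuple[list, np.ndarray]:
        """Collapse to unique sequences with summed multiplicities."""
        agg: dict[str, int] = {}
        for s, m in zip(self.sequences, self.multiplicities):
            agg[s] = agg.get(s, 0) + int(m)
        seqs = list(agg)
        return seqs, np.array([agg[s] for s in seqs], dtype=np.int64)

    @classmethod
    def from_sequences(cls, sequences, multiplicities=None) -> "AlignedReadSet":
        if multiplicities is None:
            multiplicities = np.ones(len(sequences), dtype=np.int64)
        return cls(sequences=list(sequences), multiplicities=multiplicities)

    @classmethod
    def from_fasta(cls, path) -> "AlignedReadSet":
        """Read aligned FASTA; an ``;size=N`` id suffix sets multiplicity."""
        seqs, mults = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _SIZE_RE.search(rec.id)
            mults.append(int(m.group(1)) if m else 1)
            seqs.append(str(rec.seq).upper())
        return cls(sequences=seqs, multiplicities=np.array(mults, dtype=np.int64))

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=f"read_{i};size={int(m)}", description="")
            for i, (s, m) in enumerate(zip(self.sequences, self.multiplicities))
        ]
        SeqIO.write(records, str(path), "fasta")


def _encode(sequences) -> np.ndarray:
    out = np.empty((len(sequences), len(sequences[0])), dtype=np.uint8)
    for i, s in enumerate(sequences):
        out[i] = [_CODE[c] for c in s]
    return out


def _column_entropy(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) per alignment column, multiplicity-weighted."""
    total = weights.sum()
    H = np.zeros(codes.shape[1])
    for state in range(len(ALPHABET)):
        f = ((codes == state) * weights[:, None]).sum(axis=0) / total
        nz = f > 0
        H[nz] -= f[nz] * np.log2(f[nz])
    return H


def position_entropy(reads: AlignedReadSet) -> np.ndarray:
    """Per-position Shannon entropy in bits over the five residue states."""
    seqs, mults = reads.unique()
    return _column_entropy(_encode(seqs), mults)


@dataclass
class MEDNode:
    representative: str
    members: dict            # unique sequence -> count
    total: int


@dataclass
class MEDResult:
    nodes: list
    outliers: dict = field(default_factory=lambda: {"below-M": {}, "max-variation": {}})
    entropy_trace: list = field(default_factory=list)
    total_input: int = 0

    @property
    def outlier_count(self) -> int:
        return sum(sum(d.values()) for d in self.outliers.values())

    @property
    def node_count(self) -> int:
        return sum(n.total for n in self.nodes)

    def check_conservation(self) -> None:
        """Every input read is in exactly one node or the outlier pool."""
        if self.node_count + self.outlier_count != self.total_input:
            raise AssertionError(
                f"read conservation violated: {self.node_count} + "
                f"{self.outlier_count} != {self.total_input}"
            )


def _add_outliers(pool: dict, seqs, counts) -> None:
    for s, c in zip(seqs, counts):
        pool[s] = pool.get(s, 0) + int(c)


def _mismatches(codes: np.ndarray, rep_row: np.ndarray) -> np.ndarray:
    return (codes != rep_row[None, :]).sum(axis=1)


def decompose(
    reads: AlignedReadSet,
    M: int = 100,
    d: int = 1,
    max_variation: int | None = None,
    entropy_floor: float = 0.1,
    relocate_outliers: bool = False,
) -> MEDResult:
    """Entropy decomposition with minimum substantive abundance ``M``.

    Parameters mirror the oligotyping convention: ``M`` is the minimum count
    the most abundant unique sequence of a node must reach, ``d`` the number
    of positions decomposed per split (only 1 supported).  ``max_variation``
    defaults to ``round(L/100)`` mismatches from the node representative.
    With ``relocate_outliers`` set, outlier reads are re-assigned to the
    closest node representative within ``max_variation`` mismatches.
    """
    if d != 1:
        raise UnsupportedParameterError("only d=1 decomposition is supported")
    if M < 1:
        raise ValueError("M must be >= 1")
    L = reads.length
    if max_variation is None:
        max_variation = int(round(L / 100))

    seqs, counts = reads.unique()
    codes = _encode(seqs)
    order = np.arange(len(seqs))
    result = MEDResult(nodes=[], total_input=int(counts.sum()))

    def terminal(idx: np.ndarray) -> None:
        sub_counts = counts[idx]
        # representative: most abundant unique sequence (ties: first in input)
        rep_local = int(np.argmax(sub_counts))
        rep_seq = seqs[idx[rep_local]]
        if sub_counts[rep_local] < M:
            _add_outliers(result.outliers["below-M"], [seqs[i] for i in idx], sub_counts)
            return
        mm = _mismatches(codes[idx], codes[idx[rep_local]])
        far = mm > max_variation
        if far.any():
            _add_outliers(
                result.outliers["max-variation"],
                [seqs[i] for i in idx[far]],
                sub_counts[far],
            )
        keep = idx[~far]
        if counts[keep].sum() < M:
            # node fell below substantive abundance after trimming
            _add_outliers(result.outliers["below-M"], [seqs[i] for i in keep], counts[keep])
            return
        members = {seqs[i]: int(counts[i]) for i in keep}
        result.nodes.append(
            MEDNode(representative=rep_seq, members=members, total=int(counts[keep].sum()))
        )

    def split(idx: np.ndarray) -> None:
        H = _column_entropy(codes[idx], counts[idx])
        pos = int(np.argmax(H))        # ties resolved to the lowest index
        if H[pos] <= entropy_floor:
            terminal(idx)
            return
        result.entropy_trace.append((pos, float(H[pos])))
        col = codes[idx, pos]
        for state in range(len(ALPHABET)):
            grp = idx[col == state]
            if grp.size == 0:
                continue
            if counts[grp].sum() < M:
                _add_outliers(result.outliers["below-M"], [seqs[i] for i in grp], counts[grp])
            else:
                split(grp)

    split(order)

    if relocate_outliers and result.nodes:
        reps = _encode([n.representative for n in result.nodes])
        for reason in list(result.outliers):
            pool = result.outliers[reason]
            for s in list(pool):
                mm = _mismatches(reps, _encode([s])[0])
                best = int(np.argmin(mm))
                if mm[best] <= max_variation:
                    c = pool.pop(s)
                    node = result.nodes[best]
                    node.members[s] = node.members.get(s, 0) + c
                    node.total += c

    result.check_conservation()
    return result


def pairwise_identity(a: str, b: str) -> float:
    """Percent identical sites between two equal-length aligned sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) == 0:
        raise ValueError("empty sequences")
    same = sum(x == y for x, y in zip(a, b))
    return 100.0 * same / len(a)


def taxonomy_match(identity: float, coverage: float, threshold: float = 93.0) -> str:
    """Database-hit decision rule: match iff (identity + coverage)/2 >= threshold."""
    for name, v in (("identity", identity), ("coverage", coverage)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be within [0, 100], got {v}")
    return "match" if (identity + coverage) / 2.0 >= threshold else "no_relative"


def read_accounting(total_reads: int, retained_reads: int, n_samples: int) -> dict:
    """Bookkeeping for a decomposition run over a multi-sample data set.

    Given the number of quality-filtered input reads, the number retained in
    nodes and the number of samples, returns the outlier count and the mean
    retained reads per sample (the conservation identity
    nodes + outliers = input, solved for the outliers).
    """
    if retained_reads > total_reads:
        raise ValueError("retained reads exceed input reads")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return {
        "outlier_count": int(total_reads - retained_reads),
        "mean_retained_per_sample": retained_reads / n_samples,
    }
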