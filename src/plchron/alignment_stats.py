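"""Alignment I/O, site-class statistics, concatenation and column resampling.

The container is a thin taxa-by-sites byte matrix. Site classification
follows the usual parsimony conventions: a column is *polymorphic* when it
shows at least two distinct nucleotide states, *parsimony-informative* when
at least two states are each present in at least two sequences, and
*constant* otherwise, so that constant + polymorphic = L.

Ambiguity handling is switchable because published matrix summaries rarely
state their convention: by default IUPAC ambiguity codes (R, Y, ... and N)
are treated as missing, like '-' and '?'; with ``ambiguity="state"`` each
code counts as a character state of its own.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentMatrix",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "site_classes",
    "completeness",
    "concatenate",
    "bootstrap_columns",
    "subsample_columns",
]

_UNAMBIGUOUS = frozenset(b"ACGT")
_MISSING = frozenset(b"-?N")
_AMBIGUITY = frozenset(b"RYSWKMBDHV")


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentMatrix:
    """Taxa-by-sites nucleotide matrix (uppercase bytes).

    ``partitions`` records concatenation block boundaries as
    ``(name, start, stop)`` half-open column intervals.
    """

    taxa: list
    data: np.ndarray  # shape (n_taxa, L), dtype 'S1'
    partitions: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="S1")
        if self.data.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.taxa) != self.data.shape[0]:
            raise AlignmentError("taxa count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def select_taxa(self, taxa) -> "AlignmentMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return AlignmentMatrix(list(taxa), self.data[idx], list(self.partitions))

    @classmethod
    def from_strings(cls, records) -> "AlignmentMatrix":
        """Build from ``[(name, sequence), ...]`` pairs."""
        taxa = [name for name, _ in records]
        seqs = [seq.upper() for _, seq in records]
        if not seqs:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        data = np.frombuffer(
            "".join(seqs).encode(), dtype="S1"
        ).reshape(len(seqs), -1)
        return cls(taxa, data.copy())


def read_fasta(text: str) -> AlignmentMatrix:
    """Parse an aligned multi-FASTA string (case-normalized to uppercase)."""
    records = [
        (rec.id, str(rec.seq))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise AlignmentError("no FASTA records found")
    return AlignmentMatrix.from_strings(records)


def write_fasta(aln: AlignmentMatrix, width: int = 80) -> str:
    chunks = []
    for i, taxon in enumerate(aln.taxa):
        seq = aln.data[i].tobytes().decode()
        chunks.append(f">{taxon}")
        chunks.extend(seq[j : j + width] for j in range(0, len(seq), width))
    return "\n".join(chunks) + "\n"


def site_classes(aln: AlignmentMatrix, ambiguity: str = "missing") -> dict:
    """Count constant / polymorphic / parsimony-informative columns.

    ambiguity="missing": only A/C/G/T count as states.
    ambiguity="state":   each IUPAC ambiguity code is its own state
                         ('-', '?', N always missing).
    """
    if aln.length == 0:
        raise AlignmentError("empty alignment")
    if ambiguity not in ("missing", "state"):
        raise ValueError("ambiguity must be 'missing' or 'state'")
    counted = set(_UNAMBIGUOUS)
    if ambiguity == "state":
        counted |= _AMBIGUITY
    codes = np.sort(np.frombuffer(bytes(counted), dtype="S1"))
    # counts[s, j] = occurrences of state s in column j
    counts = np.zeros((len(codes), aln.length), dtype=np.int64)
    for k, c in enumerate(codes):
        counts[k] = (aln.data == c).sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    n_doubled = (counts >= 2).sum(axis=0)
    polymorphic = int((n_states >= 2).sum())
    informative = int(((n_states >= 2) & (n_doubled >= 2)).sum())
    return {
        "constant": aln.length - polymorphic,
        "polymorphic": polymorphic,
        "parsimony_informative": informative,
        "length": aln.length,
    }


def completeness(aln: AlignmentMatrix) -> float:
    """Fraction of cells that are unambiguous nucleotides (A/C/G/T)."""
    if aln.data.size == 0:
        return 0.0
    good = np.zeros(aln.data.shape, dtype=bool)
    for c in _UNAMBIGUOUS:
        good |= aln.data == bytes([c])
    return float(good.mean())


def concatenate(alns, taxon_universe=None) -> AlignmentMatrix:
    """Concatenate alignment blocks, padding absent taxa with '?'.

    Block boundaries are recorded in ``partitions``.
    """
    if not alns:
        raise AlignmentError("nothing to concatenate")
    if taxon_universe is None:
        taxon_universe = []
        for aln in alns:
            for t in aln.taxa:
                if t not in taxon_universe:
                    taxon_universe.append(t)
    else:
        taxon_universe = list(taxon_universe)
        for i, aln in enumerate(alns):
            extra = set(aln.taxa) - set(taxon_universe)
            if extra:
                raise AlignmentError(
                    f"block {i} has taxa outside universe: {sorted(extra)}"
                )
    total = sum(a.length for a in alns)
    data = np.full((len(taxon_universe), total), b"?", dtype="S1")
    partitions = []
    offset = 0
    for i, aln in enumerate(alns):
        stop = offset + aln.length
        for j, taxon in enumerate(aln.taxa):
            data[taxon_universe.index(taxon), offset:stop] = aln.data[j]
        partitions.append((f"block{i}", offset, stop))
        offset = stop
    return AlignmentMatrix(taxon_universe, data, partitions)


def bootstrap_columns(aln: AlignmentMatrix, seed: int) -> AlignmentMatrix:
    """One nonparametric bootstrap pseudo-replicate: L columns drawn
    uniformly with replacement (same taxa, same L)."""
    if aln.length < 1:
        raise AlignmentError("cannot bootstrap an empty alignment")
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, aln.length, size=aln.length)
    return AlignmentMatrix(list(aln.taxa), aln.data[:, cols])


def subsample_columns(aln: AlignmentMatrix, n: int, seed: int) -> AlignmentMatrix:
    """n distinct columns sampled without replacement, original order kept."""
    if n > aln.length:
        raise AlignmentError(f"cannot subsample {n} of {aln.length} columns")
    if n < 0:
        raise AlignmentError("negative subsample size")
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(aln.length, size=n, replace=False))
    return AlignmentMatrix(list(aln.taxa), aln.data[:, cols])
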