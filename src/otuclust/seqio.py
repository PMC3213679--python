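"""Reading and writing sequence sets and cluster files.

A :class:`SequenceSet` keeps the two orderings the clustering algorithm
needs: residues sorted lexicographically (the implicit-trie order used by
the threshold search) and lengths sorted non-increasingly (the greedy
center-picking order).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence as TSequence

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

__all__ = ["Sequence", "SequenceSet", "read_fasta", "write_clusters", "ALPHABET"]


@dataclass(frozen=True)
class Sequence:
    """A named DNA read; residues are uppercase over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = re.search(f"[^{''.join(sorted(ALPHABET))}]", self.residues)
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid residue {bad.group()!r} "
                f"at position {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of sequences plus the two canonical orderings.

    ``lex_order[r]`` is the index of the r-th sequence when residue strings
    are sorted non-decreasingly; ``len_order[r]`` when sorted by length
    non-increasing (ties broken lexicographically by residues, then by id,
    so the ordering — and hence the whole clustering — is deterministic).
    """

    records: list[Sequence]
    lex_order: list[int] = field(init=False)
    len_order: list[int] = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen[rec.id] = i
        idx = range(len(self.records))
        self.lex_order = sorted(idx, key=lambda i: self.records[i].residues)
        self.len_order = sorted(
            idx,
            key=lambda i: (
                -len(self.records[i]),
                self.records[i].residues,
                self.records[i].id,
            ),
        )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> Sequence:
        return self.records[i]

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SequenceSet":
        return cls([Sequence(i, r.upper()) for i, r in pairs])


def read_fasta(path) -> SequenceSet:
    """Parse a (multi-)FASTA file into a :class:`SequenceSet`.

    Residues are uppercased; line wrapping is ignored. Duplicate ids,
    empty records and non-ACGTN characters raise ``ValueError``. An empty
    file yields an empty set.
    """
    records = [
        Sequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")
    ]
    return SequenceSet(records)


def write_fasta(seqs: TSequence[Sequence] | SequenceSet, sink: IO[str]) -> None:
    """Write sequences as unwrapped FASTA."""
    for rec in seqs:
        sink.write(f">{rec.id}\n{rec.residues}\n")


def write_clusters(clustering, sink: IO[str]) -> None:
    """Write one line per cluster: tab-separated member ids, representative first.

    Lines appear in order of cluster creation; members in order of
    recruitment (the representative is its own first member).
    """
    seqs = clustering.seqs
    for cluster in clustering.clusters:
        sink.write("\t".join(seqs[m.seq_index].id for m in cluster.members) + "\n")
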