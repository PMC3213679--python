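"""Star multiple sequence alignment of one cluster.

The pairwise alignments of every member against the representative fall
out of the threshold search for free; the star heuristic reconciles them
into one rectangular alignment by allocating, before each representative
position, an insertion block as wide as the longest insertion any member
places there ("once a gap, always a gap"). Members left-justify their
insertion run inside the block and pad with gaps. Because every row
differs from the representative row by at most the cluster radius, any
two rows differ column-wise by at most twice the radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

from .clusterer import Cluster
from .pairalign import AlignmentPolicy
from .seqio import SequenceSet

__all__ = ["StarMSA", "build_star_msa", "write_msa", "column_distance"]

GAP = "-"


@dataclass
class StarMSA:
    """Equal-length gapped rows; row 0 is the representative."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("alignment is not rectangular")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def _split_against_rep(query_row: str, subject_row: str, rep_len: int):
    """Per representative position: the member's insertion run before it
    and its aligned symbol at it (plus any trailing insertion run)."""
    ins: list[str] = [""] * (rep_len + 1)
    cols: list[str] = [GAP] * rep_len
    p = 0  # representative residues consumed
    for qc, sc in zip(query_row, subject_row):
        if qc == GAP:
            ins[p] += sc
        else:
            cols[p] = sc
            p += 1
    if p != rep_len:
        raise ValueError("pairwise alignment does not cover the representative")
    return ins, cols


def build_star_msa(cluster: Cluster, seqs: SequenceSet) -> StarMSA:
    """Merge the members' representative-anchored pairwise alignments."""
    rep = seqs[cluster.center].residues
    rep_len = len(rep)
    parsed = []
    for m in cluster.members:
        if m.alignment is None:
            raise ValueError(
                f"member {seqs[m.seq_index].id!r} carries no pairwise alignment"
            )
        parsed.append(_split_against_rep(m.alignment.query_row,
                                         m.alignment.subject_row, rep_len))
    widths = [0] * (rep_len + 1)
    for ins, _ in parsed:
        for p, run in enumerate(ins):
            if len(run) > widths[p]:
                widths[p] = len(run)
    ids = []
    rows = []
    for m, (ins, cols) in zip(cluster.members, parsed):
        parts = []
        for p in range(rep_len):
            parts.append(ins[p].ljust(widths[p], GAP))
            parts.append(cols[p])
        parts.append(ins[rep_len].ljust(widths[rep_len], GAP))
        ids.append(seqs[m.seq_index].id)
        rows.append("".join(parts))
    return StarMSA(ids, rows)


def column_distance(
    row_a: str, row_b: str, policy: AlignmentPolicy | None = None
) -> int:
    """Column-charged distance between two rows of one alignment.

    Mismatch or one-sided gap costs 1, match or double gap 0 — except in
    the end regions the policy leaves free: columns before the
    later-starting row's first residue and after the earlier-ending
    row's last residue are the shorter sequence's end gaps and cost
    nothing when ``anchor_start`` / ``anchor_end`` is off. Defaults to
    the 5'-anchored policy the clusterer uses.
    """
    if policy is None:
        policy = AlignmentPolicy.default()
    first = max(
        len(row_a) - len(row_a.lstrip(GAP)), len(row_b) - len(row_b.lstrip(GAP))
    )
    last = min(len(row_a.rstrip(GAP)), len(row_b.rstrip(GAP)))  # exclusive
    dist = 0
    for i, (a, b) in enumerate(zip(row_a, row_b)):
        if a == GAP and b == GAP:
            continue
        if i < first and not policy.anchor_start:
            continue
        if i >= last and not policy.anchor_end:
            continue
        if a != b or a == "N":
            dist += 1
    return dist


def write_msa(msa: StarMSA, sink: IO[str]) -> None:
    """Aligned multi-FASTA, representative first, '-' as gap."""
    for rid, row in zip(msa.ids, msa.rows):
        sink.write(f">{rid}\n{row}\n")
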