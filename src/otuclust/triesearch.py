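"""Radius-bounded search over the implicit trie of lex-sorted sequences.

The prefix tree of the candidate set is never materialized: sorting the
residue strings lexicographically makes every trie node a contiguous
sub-list, and the longest-common-prefix (LCP) of adjacent strings tells
how many dynamic-programming rows can be reused between consecutive
candidates. A depth-first traversal then amounts to a stack of banded DP
rows (one per consumed character) that is popped to the shared prefix
and pushed for the new suffix; the stack never grows beyond the longest
candidate. When a pushed row's band empties at depth α, every following
candidate sharing at least α prefix characters is skipped outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .pairalign import (
    AlignmentPolicy,
    PairwiseAlignment,
    advance_row,
    init_row,
    traceback_from_rows,
)
from .seqio import Sequence, SequenceSet

__all__ = ["SearchIndex", "SearchHit", "SearchStats", "build_index", "search_all"]


@dataclass(frozen=True)
class SearchHit:
    seq_index: int
    cost: int
    alignment: PairwiseAlignment


@dataclass
class SearchStats:
    """Work counters (row pushes = advance_row calls)."""

    rows_pushed: int = 0
    candidates_scored: int = 0


@dataclass
class SearchIndex:
    """Lex-sorted view of a sequence set with adjacent LCPs and an active mask."""

    seqs: SequenceSet
    lcp: np.ndarray = field(init=False)
    active: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        order = self.seqs.lex_order
        n = len(order)
        lcp = np.zeros(n, dtype=np.int64)
        for r in range(1, n):
            a = self.seqs[order[r - 1]].residues
            b = self.seqs[order[r]].residues
            m = min(len(a), len(b))
            k = 0
            while k < m and a[k] == b[k]:
                k += 1
            lcp[r] = k
        self.lcp = lcp
        self.active = np.ones(len(self.seqs), dtype=bool)

    def deactivate(self, seq_index: int) -> None:
        self.active[seq_index] = False


def build_index(seqs: SequenceSet) -> SearchIndex:
    return SearchIndex(seqs)


def search_all(
    index: SearchIndex,
    query: Sequence,
    policy: AlignmentPolicy,
    band_radius: int,
    accept_radius: Callable[[int], int],
    allowed: np.ndarray | None = None,
    stats: SearchStats | None = None,
) -> list[SearchHit]:
    """All active candidates within their per-length radius of ``query``.

    ``band_radius`` bounds the DP band during the descent and must be at
    least as large as ``accept_radius(len)`` for every active candidate;
    each surviving leaf is then re-checked against its own radius, so the
    hit set is exactly the brute-force one. ``allowed`` (a boolean mask
    in sequence-index space, e.g. from the k-mer filter tree) may exclude
    candidates before any DP is attempted. Candidates longer than the
    query are never eligible and are skipped.
    """
    seqs = index.seqs
    order = seqs.lex_order
    lcp = index.lcp
    nq = len(query)
    qres = query.residues
    hits: list[SearchHit] = []
    stack = [init_row(qres, policy, band_radius)]
    fail_depth: int | None = None  # depth at which the stack path died
    shared = 0  # common prefix length of stack path and current candidate
    for r, si in enumerate(order):
        if r > 0:
            s = int(lcp[r])
            if s < shared:
                shared = s
        if not index.active[si]:
            continue
        if allowed is not None and not allowed[si]:
            continue
        cand = seqs[si].residues
        if len(cand) > nq:
            continue
        if fail_depth is not None and shared >= fail_depth:
            continue  # prefix skip: shares the dead prefix
        depth = min(shared, len(stack) - 1)
        del stack[depth + 1 :]
        fail_depth = None
        row = stack[-1]
        ok = True
        for t in range(depth, len(cand)):
            row = advance_row(row, cand[t])
            if stats is not None:
                stats.rows_pushed += 1
            if not row.alive:
                fail_depth = t + 1
                ok = False
                break
            stack.append(row)
        # consumed prefix of this candidate, including the character whose
        # push emptied the band — candidates sharing it die identically
        shared = len(cand) if ok else fail_depth
        if not ok:
            continue
        if stats is not None:
            stats.candidates_scored += 1
        inf = band_radius + 1
        cost = row.costs[nq] if policy.anchor_end else row.min_cost()
        if cost < inf and cost <= accept_radius(len(cand)):
            aln = traceback_from_rows(
                stack[-(len(cand) + 1) :], qres, cand, policy
            )
            hits.append(SearchHit(si, cost, aln))
    return hits
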