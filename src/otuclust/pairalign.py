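"""Threshold-limited unit-cost edit distance and alignment traceback.

Distance model: unit cost per mismatch or per gap character, zero per
match. The subject (vertical axis of the dynamic-programming table) is
normally the shorter sequence; the query sits on the horizontal axis.
The :class:`AlignmentPolicy` decides whether gaps at the start / end of
the subject (i.e. unconsumed query prefix / suffix) are charged:

* ``anchor_start=True, anchor_end=False`` — the default: reads share a
  5' anchor, the subject may stop before the query's 3' end for free.
* ``(True, True)`` — global alignment; ``(False, False)`` — both ends of
  the shorter sequence free.

Gaps inside the alignment, and query gaps opposite subject residues, are
always charged.

All computation is confined to a band of table cells that can still stay
at or below the caller's cost threshold; values that provably exceed it
are stored as a saturating ``INF = threshold + 1``. Banded values are
bit-identical to the full-table values wherever the full value is within
threshold, which is what the trie search relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AlignmentPolicy",
    "DPRow",
    "PairwiseAlignment",
    "init_row",
    "advance_row",
    "semi_global_cost",
    "align",
    "traceback",
]


@dataclass(frozen=True)
class AlignmentPolicy:
    """Which end gaps of the shorter sequence are penalized."""

    anchor_start: bool = True
    anchor_end: bool = False

    @classmethod
    def default(cls) -> "AlignmentPolicy":
        """5'-anchored semi-global: free gaps at the 3' end only."""
        return cls(True, False)

    @classmethod
    def global_(cls) -> "AlignmentPolicy":
        return cls(True, True)

    @classmethod
    def free_both_ends(cls) -> "AlignmentPolicy":
        return cls(False, False)


class DPRow:
    """One row of the banded dynamic-programming table.

    ``costs[j]`` is the best cost of aligning the first ``depth``
    subject characters against the first ``j`` query characters, or
    ``INF = threshold+1`` where that cost provably exceeds the
    threshold. ``lo..hi`` brackets the finite entries; ``lo > hi``
    marks a dead row (no extension can come back under threshold).
    """

    __slots__ = ("query", "threshold", "anchor_start", "depth", "costs", "lo", "hi")

    def __init__(self, query, threshold, anchor_start, depth, costs, lo, hi):
        self.query = query
        self.threshold = threshold
        self.anchor_start = anchor_start
        self.depth = depth
        self.costs = costs
        self.lo = lo
        self.hi = hi

    @property
    def alive(self) -> bool:
        return self.lo <= self.hi

    def min_cost(self) -> int:
        """Minimum over the row (best free-3'-end cost at this depth)."""
        if not self.alive:
            return self.threshold + 1
        return min(self.costs[self.lo : self.hi + 1])


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows; '-' is the gap character."""

    query_row: str
    subject_row: str
    cost: int

    def __post_init__(self):
        if len(self.query_row) != len(self.subject_row):
            raise ValueError("alignment rows differ in length")


def init_row(query: str, policy: AlignmentPolicy, threshold: int) -> DPRow:
    """Depth-0 row: all zeros if the subject's start is free, else gap costs."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = len(query)
    inf = threshold + 1
    if policy.anchor_start:
        hi = min(threshold, n)
        costs = [j if j <= threshold else inf for j in range(n + 1)]
    else:
        hi = n
        costs = [0] * (n + 1)
    return DPRow(query, threshold, policy.anchor_start, 0, costs, 0, hi)


def advance_row(row: DPRow, ch: str) -> DPRow:
    """Consume one subject character; return the next row.

    Only cells that can still be within threshold are computed (the new
    band is contained in ``[lo, hi+1]`` of the previous band, because the
    cost of aligned prefixes is non-decreasing along diagonals). A dead
    row stays dead.
    """
    q = row.query
    d = row.threshold
    inf = d + 1
    n = len(q)
    depth = row.depth + 1
    new = [inf] * (n + 1)
    if not row.alive:
        return DPRow(q, d, row.anchor_start, depth, new, 1, 0)
    old = row.costs
    lo, hi = row.lo, row.hi
    nlo = -1
    nhi = -2
    start = lo
    if lo == 0:
        v = depth if depth <= d else inf
        new[0] = v
        if v <= d:
            nlo = 0
            nhi = 0
        start = 1
    stop = min(hi + 1, n)
    # 'N' never matches anything, itself included: ambiguity must not
    # create spurious proximity.
    for j in range(start, stop + 1):
        qc = q[j - 1]
        v = old[j - 1] + (0 if (qc == ch and ch != "N") else 1)
        up = old[j] + 1
        if up < v:
            v = up
        left = new[j - 1] + 1
        if left < v:
            v = left
        if v > d:
            new[j] = inf
        else:
            new[j] = v
            if nlo < 0:
                nlo = j
            nhi = j
    if nlo < 0:
        return DPRow(q, d, row.anchor_start, depth, new, 1, 0)
    return DPRow(q, d, row.anchor_start, depth, new, nlo, nhi)


def _final_cost(row: DPRow, policy: AlignmentPolicy, nq: int) -> int | None:
    inf = row.threshold + 1
    if not row.alive:
        return None
    if policy.anchor_end:
        c = row.costs[nq]
    else:
        c = row.min_cost()
    return c if c < inf else None


def _run_rows(query: str, subject: str, policy: AlignmentPolicy, threshold: int):
    rows = [init_row(query, policy, threshold)]
    for ch in subject:
        nxt = advance_row(rows[-1], ch)
        if not nxt.alive:
            return None
        rows.append(nxt)
    return rows


def semi_global_cost(
    query: str, subject: str, policy: AlignmentPolicy, threshold: int
) -> int | None:
    """Cost of the best alignment under ``policy``, or None (reject).

    None is returned iff the true cost exceeds ``threshold``; a true
    cost within threshold is always reported exactly.
    """
    rows = _run_rows(query, subject, policy, threshold)
    if rows is None:
        return None
    return _final_cost(rows[-1], policy, len(query))


def traceback_from_rows(
    rows: list[DPRow], query: str, subject: str, policy: AlignmentPolicy
) -> PairwiseAlignment:
    """Reconstruct one optimal alignment from a stack of live rows.

    Deterministic tie-break at each step: diagonal first, then a gap in
    the subject row (consume a query character), then a gap in the query
    row. With free 3' end gaps the leftmost minimal end column is chosen,
    so trailing query residues become explicit free end-gap columns.
    """
    nq = len(query)
    ns = len(subject)
    if policy.anchor_end:
        j = nq
        cost = rows[ns].costs[nq]
    else:
        last = rows[ns]
        cost = last.min_cost()
        j = rows[ns].costs.index(cost, last.lo, last.hi + 1)
    if cost > rows[ns].threshold:
        raise ValueError("traceback requested for a rejected pair")
    qcols: list[str] = []
    scols: list[str] = []
    # free (or charged-at-init) trailing end gaps
    tail = nq - j
    i = ns
    while i > 0 or j > 0:
        val = rows[i].costs[j]
        if i > 0 and j > 0:
            qc = query[j - 1]
            sc = subject[i - 1]
            sub = 0 if (qc == sc and sc != "N") else 1
            if val == rows[i - 1].costs[j - 1] + sub:
                qcols.append(qc)
                scols.append(sc)
                i -= 1
                j -= 1
                continue
        if j > 0 and (i == 0 or val == rows[i].costs[j - 1] + 1):
            if i == 0 and not policy.anchor_start:
                break  # remaining query prefix is a free start gap
            qcols.append(query[j - 1])
            scols.append("-")
            j -= 1
            continue
        qcols.append("-")
        scols.append(subject[i - 1])
        i -= 1
    head = j  # only nonzero when the start is free
    qrow = query[:head] + "".join(reversed(qcols)) + query[nq - tail :]
    srow = "-" * head + "".join(reversed(scols)) + "-" * tail
    return PairwiseAlignment(qrow, srow, cost)


def align(
    query: str, subject: str, policy: AlignmentPolicy, threshold: int
) -> PairwiseAlignment | None:
    """Cost plus one optimal alignment, or None when the pair is rejected."""
    rows = _run_rows(query, subject, policy, threshold)
    if rows is None:
        return None
    if _final_cost(rows[-1], policy, len(query)) is None:
        return None
    return traceback_from_rows(rows, query, subject, policy)


def traceback(
    query: str, subject: str, policy: AlignmentPolicy, threshold: int
) -> PairwiseAlignment:
    """As :func:`align`, but an out-of-threshold pair is an error."""
    aln = align(query, subject, policy, threshold)
    if aln is None:
        raise ValueError("pair exceeds the distance threshold")
    return aln


def symmetric_cost(
    a: str, b: str, policy: AlignmentPolicy, threshold: int
) -> int | None:
    """Orientation-free distance: best cost over both role assignments.

    The semi-global measure is asymmetric when the sequences have equal
    length (the free end gaps belong to the subject role), so the
    distance between two *members* — e.g. when evaluating a cluster's
    diameter — is taken as the minimum over the two assignments. The
    cluster-diameter guarantee (at most twice the radius) holds for this
    measure: the star alignment induces, for any member pair, an
    alignment whose policy-charged cost is within twice the radius, and
    its free end region always matches one of the two orientations.
    """
    c1 = semi_global_cost(a, b, policy, threshold)
    c2 = semi_global_cost(b, a, policy, threshold)
    if c1 is None:
        return c2
    if c2 is None:
        return c1
    return min(c1, c2)
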