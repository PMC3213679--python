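"""Completely sensitive k-mer spectrum screen and interval filter tree.

If a candidate ``s`` lies within edit distance ``d`` of some substring of
the query ``q`` (which is what any accepted semi-global alignment of a
shorter candidate means), then each of the ``d`` edits can destroy at
most ``k`` of the candidate's k-mers, so

    pos(spectrum_k(s) - spectrum_k(q)) <= k * d,

where ``pos`` sums the positive entries of the count difference. A pair
violating the bound can be rejected without any alignment; a pair within
distance never violates it, so the screen is completely sensitive. Note
the direction: the candidate's spectrum is the minuend — the longer
query is allowed arbitrarily many k-mers the candidate lacks.

The filter tree extends the test to whole sub-lists of the lex-sorted
sequence list: each node covers a contiguous interval and stores
element-wise lower/upper bounds over the covered spectra. In exact mode
a node is discarded only when the lower bound already violates the
candidate-side inequality, which cannot hold for any covered true hit.
The approximate mode additionally prunes on an optimistic shared-k-mer
count and may lose true hits (documented lossy; it can only split
clusters, never corrupt them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .triesearch import SearchIndex

__all__ = [
    "KmerSpectrum",
    "FilterTree",
    "FilterNode",
    "spectrum",
    "pos_neg_diff",
    "may_match",
    "build_filter_tree",
    "prune",
]

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i

EXACT = "exact"
APPROXIMATE = "approximate"


@dataclass(frozen=True)
class KmerSpectrum:
    """Dense count vector over the 4^k k-mers of one sequence.

    k-mers containing 'N' are not counted; ``dropped`` records how many
    windows were lost that way. For an N-free sequence of length n >= k,
    ``counts.sum() == n - k + 1``.
    """

    k: int
    counts: np.ndarray
    dropped: int = 0

    def pos(self) -> int:
        return int(self.counts[self.counts > 0].sum())


def spectrum(residues: str, k: int) -> KmerSpectrum:
    """Count all overlapping k-mers of ``residues``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(residues)
    size = 4**k
    if n < k:
        return KmerSpectrum(k, np.zeros(size, dtype=np.int32), 0)
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    ids = win[valid] @ weights
    counts = np.bincount(ids, minlength=size).astype(np.int32)
    return KmerSpectrum(k, counts, int((~valid).sum()))


def pos_neg_diff(a: KmerSpectrum, b: KmerSpectrum) -> tuple[int, int]:
    """(pos, neg) of the element-wise count difference a - b."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    diff = a.counts.astype(np.int64) - b.counts
    return int(diff[diff > 0].sum()), int(diff[diff < 0].sum())


def may_match(query_spec: KmerSpectrum, cand_spec: KmerSpectrum, d: int) -> bool:
    """False only when no alignment of the candidate within the query can
    cost <= d; never false for a true within-threshold pair.

    Dropping the candidate's N-containing k-mers only lowers the
    candidate-side sum, so it keeps the test conservative. Dropped
    k-mers on the *query* side would not, so a query containing 'N'
    disables the screen entirely.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if query_spec.k != cand_spec.k:
        raise ValueError(f"k mismatch: {query_spec.k} != {cand_spec.k}")
    if query_spec.dropped:
        return True
    pos, _ = pos_neg_diff(cand_spec, query_spec)
    return pos <= query_spec.k * d


@dataclass
class FilterNode:
    """Covers lex-order interval [lo, hi); bounds are element-wise over spectra."""

    lo: int
    hi: int
    lower: np.ndarray
    upper: np.ndarray
    min_len: int
    max_len: int
    left: "FilterNode | None" = None
    right: "FilterNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class FilterTree:
    k: int
    root: "FilterNode | None"
    index: SearchIndex

    def nodes(self) -> Iterator[FilterNode]:
        stack = [self.root] if self.root else []
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.extend((node.left, node.right))

    def query_mask(
        self, query_spec: KmerSpectrum, query_len: int, d: int, mode: str = EXACT
    ) -> np.ndarray:
        """Boolean mask over sequence indices left standing by the filter."""
        seqs = self.index.seqs
        order = seqs.lex_order
        mask = np.zeros(len(seqs), dtype=bool)
        if self.root is None:
            return mask

        def visit(node: FilterNode) -> None:
            if node.min_len > query_len:
                return  # no covered candidate is eligible
            if prune(node, query_spec, d, mode, query_len):
                return
            if node.is_leaf:
                for r in range(node.lo, node.hi):
                    mask[order[r]] = True
            else:
                visit(node.left)
                visit(node.right)

        visit(self.root)
        return mask


def build_filter_tree(index: SearchIndex, k: int, leaf_size: int = 16) -> FilterTree:
    """Balanced interval tree over the lex-sorted list with spectral bounds."""
    seqs = index.seqs
    order = seqs.lex_order
    n = len(order)
    if n == 0:
        return FilterTree(k, None, index)
    specs = [spectrum(seqs[si].residues, k) for si in order]
    mat = np.stack([sp.counts for sp in specs])
    lens = np.array([len(seqs[si]) for si in order])

    def build(lo: int, hi: int) -> FilterNode:
        if hi - lo <= leaf_size:
            return FilterNode(
                lo,
                hi,
                mat[lo:hi].min(axis=0),
                mat[lo:hi].max(axis=0),
                int(lens[lo:hi].min()),
                int(lens[lo:hi].max()),
            )
        mid = (lo + hi) // 2
        left = build(lo, mid)
        right = build(mid, hi)
        return FilterNode(
            lo,
            hi,
            np.minimum(left.lower, right.lower),
            np.maximum(left.upper, right.upper),
            min(left.min_len, right.min_len),
            max(left.max_len, right.max_len),
            left,
            right,
        )

    return FilterTree(k, build(0, n), index)


def prune(
    node: FilterNode,
    query_spec: KmerSpectrum,
    d: int,
    mode: str = EXACT,
    query_len: int | None = None,
) -> bool:
    """True when the whole interval can be skipped for this query.

    Exact mode: skip only when even the element-wise lower bound of the
    covered spectra violates the candidate-side inequality — then every
    covered sequence violates it, so no true hit is lost. Approximate
    mode additionally skips when an optimistic shared-k-mer count (query
    vs. the element-wise upper bound) falls short of what the shortest
    eligible covered sequence would need with an edit budget tightened
    by one (never below zero). A true hit whose edits all land with full
    k-mer impact can fail that tightened budget, so the mode is lossy;
    the screen stays robust to free 3' truncations because the
    requirement follows the shortest covered length.
    """
    k = query_spec.k
    if query_spec.dropped:
        return False
    q = query_spec.counts.astype(np.int64)
    diff = node.lower - q
    if int(diff[diff > 0].sum()) > k * d:
        return True
    if mode == APPROXIMATE:
        shared_opt = int(np.minimum(q, node.upper).sum())
        cap = node.min_len if query_len is None else min(node.min_len, query_len)
        needed = (cap - k + 1) - k * max(d - 1, 0)
        if shared_opt < needed:
            return True
    elif mode != EXACT:
        raise ValueError(f"unknown filter mode: {mode!r}")
    return False
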