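"""Greedy radius-bounded clustering and the well-separated variant.

The similarity threshold ``s`` in (0, 1] is converted to an integer edit
radius per sequence length: a member of length L (L is always the
shorter of the pair, since centers are picked longest-first) may sit at
cost ``floor((1 - s) * L)`` from its representative, the largest cost at
which ``1 - cost / L >= s`` still holds.

Each round picks the longest unclustered sequence as a new center, finds
every unclustered sequence within its length-dependent radius with the
trie search (optionally screened by the k-mer filter tree), recruits all
of them and never revisits them. With the complete (exact-mode) filter
the result is a *valid* and *exact* clustering: every member within
threshold of its representative, every pair of representatives farther
apart than the threshold. The well-separated variant searches to twice
the radius, recruits within the radius and flags the rest as ineligible
to seed clusters, so that surviving centers are pairwise more than two
radii apart; flagged sequences that never get recruited end up as
singleton clusters, marked ``leftover``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .kmerfilter import EXACT, build_filter_tree, spectrum
from .pairalign import AlignmentPolicy, PairwiseAlignment
from .seqio import SequenceSet
from .triesearch import SearchIndex, SearchStats, build_index, search_all

__all__ = [
    "ClusterParams",
    "Member",
    "Cluster",
    "Clustering",
    "radius_for",
    "greedy_cluster",
    "greedy_cluster_well_separated",
]

STANDARD = "standard"
WELL_SEPARATED = "well_separated"


@dataclass(frozen=True)
class ClusterParams:
    similarity: float = 0.99
    policy: AlignmentPolicy = field(default_factory=AlignmentPolicy.default)
    k: int = 3
    filter_mode: str | None = EXACT  # "exact", "approximate" or None (no filter)
    separation: str = STANDARD

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity <= 1.0):
            raise ValueError("similarity must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class Member:
    seq_index: int
    cost: int
    alignment: PairwiseAlignment


@dataclass
class Cluster:
    """One cluster: the representative is its own first member at cost 0."""

    center: int
    members: list[Member]
    radius_bound: int
    leftover: bool = False


@dataclass
class Clustering:
    clusters: list[Cluster]
    params: ClusterParams
    seqs: SequenceSet

    def __len__(self) -> int:
        return len(self.clusters)

    def assignment(self) -> dict[str, str]:
        """Map member id -> representative id."""
        out: dict[str, str] = {}
        for cl in self.clusters:
            rep = self.seqs[cl.center].id
            for m in cl.members:
                out[self.seqs[m.seq_index].id] = rep
        return out


def radius_for(similarity: float, shorter_len: int) -> int:
    """Largest integer cost c with 1 - c/shorter_len >= similarity.

    A small epsilon absorbs binary-float error in (1 - s) * L so that
    thresholds like 0.90 at length 50 give exactly 5, not 4.
    """
    if shorter_len < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 < similarity <= 1.0):
        raise ValueError("similarity must be in (0, 1]")
    return int(math.floor((1.0 - similarity) * shorter_len + 1e-9))


def _greedy(seqs: SequenceSet, params: ClusterParams) -> Clustering:
    index = build_index(seqs)
    tree = (
        build_filter_tree(index, params.k) if params.filter_mode is not None else None
    )
    well_sep = params.separation == WELL_SEPARATED
    sim = params.similarity
    flagged = [False] * len(seqs)
    clusters: list[Cluster] = []
    stats = SearchStats()
    for ci in seqs.len_order:
        if not index.active[ci]:
            continue
        if flagged[ci]:
            continue
        center = seqs[ci]
        r_center = radius_for(sim, len(center))
        band = 2 * r_center if well_sep else r_center

        if well_sep:
            def accept(length: int) -> int:
                return 2 * radius_for(sim, length)
        else:
            def accept(length: int) -> int:
                return radius_for(sim, length)

        allowed = None
        if tree is not None:
            qspec = spectrum(center.residues, params.k)
            allowed = tree.query_mask(qspec, len(center), band, params.filter_mode)
        hits = search_all(
            index, center, params.policy, band, accept, allowed=allowed, stats=stats
        )
        members: list[Member] = []
        for hit in hits:
            r_hit = radius_for(sim, len(seqs[hit.seq_index]))
            if hit.cost <= r_hit:
                members.append(Member(hit.seq_index, hit.cost, hit.alignment))
                index.deactivate(hit.seq_index)
            elif well_sep and hit.cost <= 2 * r_hit:
                flagged[hit.seq_index] = True
        if not any(m.seq_index == ci for m in members):
            # the lossy approximate filter may screen out even the center's
            # own interval; the center still anchors its cluster
            aln = PairwiseAlignment(center.residues, center.residues, 0)
            members.append(Member(ci, 0, aln))
            index.deactivate(ci)
        # the center found itself at cost 0; put it first
        members.sort(key=lambda m: m.seq_index != ci)
        clusters.append(Cluster(ci, members, r_center))
    if well_sep:
        # flagged sequences no cluster recruited: emit as labeled singletons
        for ci in seqs.len_order:
            if index.active[ci]:
                center = seqs[ci]
                aln = PairwiseAlignment(center.residues, center.residues, 0)
                clusters.append(
                    Cluster(
                        ci,
                        [Member(ci, 0, aln)],
                        radius_for(sim, len(center)),
                        leftover=True,
                    )
                )
                index.deactivate(ci)
    return Clustering(clusters, params, seqs)


def greedy_cluster(seqs: SequenceSet, params: ClusterParams) -> Clustering:
    """Greedy longest-first clustering (standard mode)."""
    if params.separation == WELL_SEPARATED:
        return greedy_cluster_well_separated(seqs, params)
    return _greedy(seqs, params)


def greedy_cluster_well_separated(
    seqs: SequenceSet, params: ClusterParams
) -> Clustering:
    """Well-separated clustering: centers pairwise farther than twice the radius."""
    if params.separation != WELL_SEPARATED:
        params = ClusterParams(
            params.similarity, params.policy, params.k, params.filter_mode,
            WELL_SEPARATED,
        )
    return _greedy(seqs, params)
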