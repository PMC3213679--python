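"""Synthetic "center + error cloud" read sets with known ground truth.

The generator emulates the regime the clustering targets: a few distinct
template molecules, each observed many times with a small number of
sequencing errors. Templates are drawn at random and rejection-sampled
until every pair is separated by more than twice the largest admissible
radius, so each cloud is recoverable as exactly one cluster. Reads derive
from their template by substitutions and internal deletions whose count
never exceeds the radius the similarity threshold grants the read's
final length, plus an optional (free under the default 5'-anchored
policy) 3' truncation. Any erroneous read loses at least one base, so
the error-free template is always the longest — and lexicographically
first among equals — read of its cloud, which is what makes greedy
longest-first recovery exact.

Insertions are deliberately not generated: a read longer than its
template could be picked as a center before the template, and recovery
of the planted partition would no longer be guaranteed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO

import numpy as np

from .clusterer import radius_for
from .pairalign import AlignmentPolicy, semi_global_cost
from .seqio import Sequence, SequenceSet

__all__ = ["CloudConfig", "CloudTruth", "generate_clouds", "write_truth"]

_BASES = "ACGT"


@dataclass(frozen=True)
class CloudConfig:
    """Study conditions for one synthetic read set.

    Defaults emulate a pyrosequencing amplicon run clustered at 99%
    identity: reads a couple of hundred bp long, sub-percent error rate,
    tens of reads per template.
    """

    n_centers: int = 10
    cloud_size: int = 20
    mutation_rate: float = 0.005  # per-base substitution/deletion probability
    length_range: tuple[int, int] = (200, 260)
    similarity: float = 0.99
    max_truncation_frac: float = 0.1
    seed: int = 0
    max_center_retries: int = 1000


@dataclass
class CloudTruth:
    """Planted assignment: read id -> (template id, charged edit count)."""

    center_of: dict[str, str] = field(default_factory=dict)
    edits_of: dict[str, int] = field(default_factory=dict)

    def partition(self) -> dict[str, set[str]]:
        groups: dict[str, set[str]] = {}
        for rid, cid in self.center_of.items():
            groups.setdefault(cid, set()).add(rid)
        return groups


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(
    rng: np.random.Generator, template: str, d_cap_fn, rate: float, max_trunc: int
) -> tuple[str, int]:
    """Apply charged edits (subs/deletions) plus a free 3' truncation.

    The charged edit count is capped so the read stays within the radius
    its own final length is granted; at least one base is removed
    whenever the read is not an exact copy, keeping the template longest.
    """
    n = len(template)
    n_edits = int(rng.binomial(n, rate))
    trunc = int(rng.integers(0, max_trunc + 1)) if max_trunc > 0 else 0
    if n_edits > 0 and trunc == 0:
        trunc = 1
    while True:
        # deletions shorten the read, which can shrink its own radius;
        # shed edits until the charged count fits the final length
        kinds = rng.random(n_edits) < 0.25 if n_edits else np.array([], dtype=bool)
        n_dels = int(kinds.sum())
        final_len = n - trunc - n_dels
        if final_len >= 1 and n_edits <= d_cap_fn(final_len):
            break
        n_edits -= 1
    body = list(template[: n - trunc])
    positions = rng.choice(len(body), size=min(n_edits, len(body)), replace=False)
    charged = 0
    for pos, is_del in sorted(zip(positions.tolist(), kinds.tolist()), reverse=True):
        if is_del:
            del body[pos]
        else:
            old = body[pos]
            body[pos] = _BASES[(_BASES.index(old) + int(rng.integers(1, 4))) % 4]
        charged += 1
    read = "".join(body)
    if not read:
        return template, 0
    return read, charged


def generate_clouds(
    config: CloudConfig, policy: AlignmentPolicy | None = None
) -> tuple[SequenceSet, CloudTruth]:
    """Draw templates and their error clouds; return reads plus truth table.

    Raises ``RuntimeError`` when well-separated templates cannot be found
    within the retry budget (longer sequences or fewer centers help).
    """
    if policy is None:
        policy = AlignmentPolicy.default()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length range")
    d_max = radius_for(config.similarity, hi)
    sep = 2 * d_max
    centers: list[str] = []
    tries = 0
    while len(centers) < config.n_centers:
        tries += 1
        if tries > config.max_center_retries * config.n_centers:
            raise RuntimeError(
                "could not draw pairwise-separated templates; "
                "try longer sequences or fewer centers"
            )
        cand = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        ok = True
        for c in centers:
            a, b = (c, cand) if len(c) >= len(cand) else (cand, c)
            if semi_global_cost(a, b, policy, sep) is not None:
                ok = False
                break
        if ok:
            centers.append(cand)
    records: list[Sequence] = []
    truth = CloudTruth()
    width = len(str(config.n_centers * config.cloud_size))
    for ci, template in enumerate(centers):
        cid = f"C{ci:0{width}d}"
        records.append(Sequence(cid, template))
        truth.center_of[cid] = cid
        truth.edits_of[cid] = 0
        max_trunc = int(len(template) * config.max_truncation_frac)
        for ri in range(config.cloud_size):
            read, charged = _mutate(
                rng,
                template,
                lambda L: radius_for(config.similarity, L),
                config.mutation_rate,
                max_trunc,
            )
            rid = f"C{ci:0{width}d}R{ri:0{width}d}"
            records.append(Sequence(rid, read))
            truth.center_of[rid] = cid
            truth.edits_of[rid] = charged
    return SequenceSet(records), truth


def write_truth(truth: CloudTruth, sink: IO[str] = sys.stdout) -> None:
    """Tab-separated truth table: read id, template id, charged edits."""
    sink.write("read_id\tcenter_id\tedits\n")
    for rid in truth.center_of:
        sink.write(f"{rid}\t{truth.center_of[rid]}\t{truth.edits_of[rid]}\n")
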