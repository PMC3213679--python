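"""Independent oracles for the test suite.

Everything here recomputes quantities by a route deliberately different
from the package: full (unbanded) dynamic-programming tables vectorized
with numpy, dictionary-based k-mer counting, character-by-character LCP
scans, and edlib for the alignment modes it supports.
"""

from __future__ import annotations

import numpy as np

from otuclust.pairalign import AlignmentPolicy

BASES = "ACGT"


def full_matrix_cost(query: str, subject: str, policy: AlignmentPolicy) -> int:
    """Unbanded unit-cost alignment of subject (vertical) vs query."""
    nq = len(query)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    n_code = ord("N")
    if policy.anchor_start:
        row = np.arange(nq + 1, dtype=np.int64)
    else:
        row = np.zeros(nq + 1, dtype=np.int64)
    idx = np.arange(nq + 1, dtype=np.int64)
    for ch in subject.encode():
        sub = np.where((q == ch) & (ch != n_code) & (q != n_code), 0, 1)
        new = np.empty_like(row)
        new[0] = row[0] + 1
        new[1:] = np.minimum(row[:-1] + sub, row[1:] + 1)
        # close under left-gap moves: new[j] = min_i<=j new[i] + (j - i)
        new = np.minimum.accumulate(new - idx) + idx
        row = new
    return int(row[nq]) if policy.anchor_end else int(row.min())


def full_matrix_rows(query: str, subject: str, policy: AlignmentPolicy):
    """All rows of the unbanded table (for banded-equivalence checks)."""
    rows = []
    nq = len(query)
    if policy.anchor_start:
        row = list(range(nq + 1))
    else:
        row = [0] * (nq + 1)
    rows.append(row)
    for sc in subject:
        prev = rows[-1]
        new = [prev[0] + 1]
        for j in range(1, nq + 1):
            qc = query[j - 1]
            sub = 0 if (qc == sc and sc != "N" and qc != "N") else 1
            new.append(min(prev[j - 1] + sub, prev[j] + 1, new[j - 1] + 1))
        rows.append(new)
    return rows


def brute_force_hits(seqs, active, query, policy, accept_radius):
    """{seq_index: cost} over active candidates not longer than the query."""
    out = {}
    for i, rec in enumerate(seqs):
        if not active[i] or len(rec) > len(query):
            continue
        cost = full_matrix_cost(query.residues, rec.residues, policy)
        if cost <= accept_radius(len(rec)):
            out[i] = cost
    return out


def naive_lcp(a: str, b: str) -> int:
    k = 0
    m = min(len(a), len(b))
    while k < m and a[k] == b[k]:
        k += 1
    return k


def dict_spectrum(residues: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(residues) - k + 1):
        w = residues[i : i + k]
        if "N" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_within(rng: np.random.Generator, seq: str, d: int) -> str:
    """Apply at most d random edits (sub/ins/del) to seq."""
    s = list(seq)
    for _ in range(int(rng.integers(0, d + 1))):
        kind = int(rng.integers(0, 3))
        if not s:
            kind = 1
        if kind == 0:
            p = int(rng.integers(0, len(s)))
            s[p] = BASES[(BASES.index(s[p]) + int(rng.integers(1, 4))) % 4]
        elif kind == 1:
            p = int(rng.integers(0, len(s) + 1))
            s.insert(p, BASES[int(rng.integers(0, 4))])
        else:
            p = int(rng.integers(0, len(s)))
            del s[p]
    return "".join(s) if s else seq
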