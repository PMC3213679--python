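import numpy as np
import pytest

from otuclust import AlignmentPolicy, SequenceSet

POLICIES = {
    "anchored-5p": AlignmentPolicy.default(),
    "global": AlignmentPolicy.global_(),
    "free-both-ends": AlignmentPolicy.free_both_ends(),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def make_random_set(rng):
    """Factory for random SequenceSets (uniform residues, given lengths)."""

    def _make(n, len_lo, len_hi, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        pairs = []
        for i in range(n):
            length = int(r.integers(len_lo, len_hi + 1))
            pairs.append(
                (f"s{i}", "".join("ACGT"[b] for b in r.integers(0, 4, size=length)))
            )
        return SequenceSet.from_pairs(pairs)

    return _make
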