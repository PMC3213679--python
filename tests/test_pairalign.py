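import itertools

import edlib
import numpy as np
import pytest

from otuclust.pairalign import (
    AlignmentPolicy,
    advance_row,
    align,
    init_row,
    semi_global_cost,
    traceback,
)

from conftest import POLICIES
from oracle import full_matrix_cost, full_matrix_rows, random_dna

DEFAULT = AlignmentPolicy.default()
GLOBAL = AlignmentPolicy.global_()


class TestInitRow:
    def test_free_start_all_zeros(self):
        row = init_row("ACGT", AlignmentPolicy.free_both_ends(), 2)
        assert row.costs == [0, 0, 0, 0, 0]
        assert (row.lo, row.hi) == (0, 4)

    def test_anchored_start_gap_costs_clipped(self):
        row = init_row("ACGT", GLOBAL, 2)
        assert row.costs == [0, 1, 2, 3, 3]  # 3 == INF sentinel
        assert (row.lo, row.hi) == (0, 2)

    def test_zero_threshold_free_start_band_spans_row(self):
        row = init_row("ACGTACGT", AlignmentPolicy.free_both_ends(), 0)
        assert (row.lo, row.hi) == (0, 8)


class TestAdvanceRow:
    def test_row_minima_track_matches_and_mismatch(self):
        row = init_row("AAAA", DEFAULT, 1)
        row = advance_row(row, "A")
        assert row.min_cost() == 0
        row = advance_row(row, "A")
        assert row.min_cost() == 0
        row = advance_row(row, "C")
        assert row.min_cost() == 1

    def test_dead_row_is_absorbing(self):
        row = init_row("AAAA", DEFAULT, 0)
        for ch in "CC":
            row = advance_row(row, ch)
        assert not row.alive
        assert not advance_row(row, "A").alive

    def test_n_never_matches_even_itself(self):
        assert semi_global_cost("ANAT", "ANAT", GLOBAL, 2) == 1

    @pytest.mark.parametrize("policy_name", list(POLICIES))
    def test_banded_rows_equal_full_matrix_within_threshold(self, rng, policy_name):
        policy = POLICIES[policy_name]
        for _ in range(300):
            nq = int(rng.integers(1, 40))
            ns = int(rng.integers(1, 40))
            query = random_dna(rng, nq)
            subject = random_dna(rng, ns)
            d = int(rng.integers(0, 6))
            full = full_matrix_rows(query, subject, policy)
            row = init_row(query, policy, d)
            for i, ch in enumerate(subject, start=1):
                row = advance_row(row, ch)
                for j, truth in enumerate(full[i]):
                    if truth <= d:
                        assert row.costs[j] == truth
                    else:
                        assert row.costs[j] > d
                if not row.alive:
                    assert min(full[i]) > d
                    break

    def test_row_minima_monotone_non_decreasing(self, rng):
        for _ in range(100):
            query = random_dna(rng, int(rng.integers(5, 30)))
            subject = random_dna(rng, int(rng.integers(5, 30)))
            row = init_row(query, DEFAULT, 3)
            prev = row.min_cost()
            for ch in subject:
                row = advance_row(row, ch)
                if not row.alive:
                    break
                assert row.min_cost() >= prev
                prev = row.min_cost()


class TestSemiGlobalCost:
    def test_free_3prime_gap_costs_nothing(self):
        assert semi_global_cost("ACGTT", "ACG", DEFAULT, 2) == 0

    def test_identity_any_policy_zero_threshold(self):
        for policy in POLICIES.values():
            assert semi_global_cost("ACGT", "ACGT", policy, 0) == 0

    @pytest.mark.parametrize("policy_name", list(POLICIES))
    def test_matches_full_matrix_or_rejects(self, rng, policy_name):
        policy = POLICIES[policy_name]
        for _ in range(400):
            query = random_dna(rng, int(rng.integers(10, 61)))
            subject = random_dna(rng, int(rng.integers(5, len(query) + 1)))
            d = int(rng.integers(0, 6))
            truth = full_matrix_cost(query, subject, policy)
            got = semi_global_cost(query, subject, policy, d)
            assert got == (truth if truth <= d else None)

    def test_agrees_with_edlib_modes(self, rng):
        # independent oracle: edlib NW == our global, SHW == our default
        for _ in range(200):
            query = random_dna(rng, int(rng.integers(10, 50)))
            subject = random_dna(rng, int(rng.integers(5, len(query) + 1)))
            nw = edlib.align(subject, query, mode="NW")["editDistance"]
            shw = edlib.align(subject, query, mode="SHW")["editDistance"]
            assert semi_global_cost(query, subject, GLOBAL, 60) == nw
            assert semi_global_cost(query, subject, DEFAULT, 60) == shw


class TestMetricProperties:
    def test_global_cost_is_a_metric_on_random_triples(self, rng):
        big = 1000
        for _ in range(150):
            a, b, c = (random_dna(rng, int(rng.integers(5, 25))) for _ in range(3))
            dab = semi_global_cost(a, b, GLOBAL, big)
            dba = semi_global_cost(b, a, GLOBAL, big)
            dac = semi_global_cost(a, c, GLOBAL, big)
            dbc = semi_global_cost(b, c, GLOBAL, big)
            assert dab == dba
            assert semi_global_cost(a, a, GLOBAL, big) == 0
            assert dac <= dab + dbc

    def test_identity_of_indiscernibles(self, rng):
        for _ in range(50):
            a = random_dna(rng, int(rng.integers(3, 20)))
            b = random_dna(rng, len(a))
            d = semi_global_cost(a, b, GLOBAL, 1000)
            assert (d == 0) == (a == b)


class TestTraceback:
    def test_identity(self):
        aln = traceback("ACGT", "ACGT", DEFAULT, 0)
        assert (aln.query_row, aln.subject_row, aln.cost) == ("ACGT", "ACGT", 0)

    def test_free_end_gap_shown_explicitly(self):
        aln = traceback("ACGTT", "ACG", DEFAULT, 2)
        assert (aln.query_row, aln.subject_row, aln.cost) == ("ACGTT", "ACG--", 0)

    def test_rejected_pair_is_an_error(self):
        with pytest.raises(ValueError):
            traceback("AAAA", "CCCC", DEFAULT, 1)

    @pytest.mark.parametrize("policy_name", list(POLICIES))
    def test_column_charged_cost_consistent(self, rng, policy_name):
        """Degapping recovers inputs; recharging columns recovers the cost."""
        policy = POLICIES[policy_name]
        checked = 0
        while checked < 200:
            query = random_dna(rng, int(rng.integers(5, 40)))
            subject = "".join(
                ch for ch in query[: int(rng.integers(3, len(query) + 1))]
            )
            # mutate slightly so alignments are non-trivial
            if rng.random() < 0.7 and len(subject) > 2:
                p = int(rng.integers(0, len(subject)))
                subject = subject[:p] + subject[p + 1 :]
            d = int(rng.integers(0, 6))
            aln = align(query, subject, policy, d)
            if aln is None:
                continue
            checked += 1
            assert aln.query_row.replace("-", "") == query
            assert aln.subject_row.replace("-", "") == subject
            charged = _charge(aln.query_row, aln.subject_row, policy)
            assert charged == aln.cost == semi_global_cost(query, subject, policy, d)


def _charge(qrow, srow, policy):
    """Recompute an alignment's cost from its columns under the policy."""
    n = len(srow)
    start = n - len(srow.lstrip("-"))
    end = len(srow.rstrip("-"))
    cost = 0
    for i, (qc, sc) in enumerate(zip(qrow, srow)):
        if sc == "-" and qc != "-":
            before, after = i < start, i >= end
            if before and not policy.anchor_start:
                continue
            if after and not policy.anchor_end:
                continue
            cost += 1
        elif qc == "-" or qc != sc or qc == "N":
            cost += 1
    return cost


def test_exhaustive_tiny_pairs_match_oracle():
    """Every pair of length-<=3 sequences over {A,C}, every policy, d=0..4."""
    seqs = [
        "".join(t)
        for n in (1, 2, 3)
        for t in itertools.product("AC", repeat=n)
    ]
    for policy in POLICIES.values():
        for query in seqs:
            for subject in seqs:
                if len(subject) > len(query):
                    continue
                truth = full_matrix_cost(query, subject, policy)
                for d in range(5):
                    got = semi_global_cost(query, subject, policy, d)
                    assert got == (truth if truth <= d else None)


class TestSymmetricCost:
    def test_symmetric_and_bounded_by_both_orientations(self, rng):
        from otuclust.pairalign import symmetric_cost

        for _ in range(150):
            a = random_dna(rng, int(rng.integers(5, 30)))
            b = random_dna(rng, int(rng.integers(5, 30)))
            want = min(
                full_matrix_cost(a, b, DEFAULT), full_matrix_cost(b, a, DEFAULT)
            )
            got = symmetric_cost(a, b, DEFAULT, 100)
            assert got == symmetric_cost(b, a, DEFAULT, 100) == want

    def test_rejects_when_both_orientations_exceed_threshold(self):
        from otuclust.pairalign import symmetric_cost

        assert symmetric_cost("AAAAAA", "CCCCCC", DEFAULT, 2) is None
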