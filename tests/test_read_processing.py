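"""Extraction, alignment, classification and yield statistics."""

import math

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eoskit.read_processing import (
    align_to_target,
    classify_errors,
    compute_metrics,
    extract_payload,
    extract_payloads,
    per_position_profile,
    stepwise_yield,
)
from eoskit.simulate import ErrorModel, ReadLayout, SimulationRun, simulate_run
from eoskit.targets import INITIATOR_ANCHOR

ANCHOR = INITIATOR_ANCHOR


def brute_force_edit_distance(a: str, b: str) -> int:
    """Independent oracle: enumerate alignments recursively (tiny inputs only)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        brute_force_edit_distance(a[1:], b[1:]) + (a[0] != b[0]),
        brute_force_edit_distance(a[1:], b) + 1,
        brute_force_edit_distance(a, b[1:]) + 1,
    )


class TestExtraction:
    def test_clean_read(self, nine_mer):
        hit = extract_payload(ANCHOR + nine_mer + "A" * 20)
        assert hit is not None
        assert hit.payload == nine_mer
        assert hit.strand == "forward"

    def test_zero_length_payload_is_present(self):
        hit = extract_payload(ANCHOR + "A" * 20)
        assert hit is not None
        assert hit.payload == ""

    def test_read_without_polya_is_absent(self):
        assert extract_payload(ANCHOR + "GCGCGC") is None

    def test_reverse_complement_searched(self, nine_mer):
        from eoskit.read_processing import reverse_complement

        fwd = ANCHOR + nine_mer + "A" * 20
        hit = extract_payload(reverse_complement(fwd))
        assert hit is not None
        assert hit.payload == nine_mer
        assert hit.strand == "reverse"

    def test_extraction_is_non_greedy(self):
        # payload then tail; a second A-run later must not extend the match
        read = ANCHOR + "GCT" + "A" * 20 + "GG" + "A" * 12
        assert extract_payload(read).payload == "GCT"

    def test_unmatched_reads_counted(self, nine_mer):
        reads = [ANCHOR + nine_mer + "A" * 20, "GGGG"]
        hits, absent = extract_payloads(reads)
        assert len(hits) == 1 and absent == 1


class TestAlignment:
    def test_identity_alignment(self, nine_mer):
        aln = align_to_target(nine_mer, nine_mer)
        assert aln.score == 0
        assert all(op == "match" for op, _, _ in aln.ops)

    def test_three_deletions(self, nine_mer):
        aln = align_to_target("GCTGCT", nine_mer)
        ops = [op for op, _, _ in aln.ops]
        assert aln.score == 3
        assert ops.count("deletion") == 3 and ops.count("match") == 6

    def test_substitution_position(self):
        aln = align_to_target("CAC", "CCC")
        assert aln.score == 1
        assert ("substitution", 1, 1) in aln.ops

    def test_empty_payload_is_all_deletions(self, nine_mer):
        aln = align_to_target("", nine_mer)
        assert aln.score == 9
        assert all(op == "deletion" for op, _, _ in aln.ops)

    def test_deletions_placed_leftmost_in_homopolymer(self):
        aln = align_to_target("CC", "CCC")
        assert aln.ops[0] == ("deletion", 0, -1)

    def test_cost_matches_edlib_on_random_pairs(self, rng):
        for _ in range(300):
            a = "".join(rng.choice(list("ACGT"), rng.integers(0, 12)))
            t = "".join(rng.choice(list("ACGT"), rng.integers(1, 12)))
            expected = edlib.align(a, t, task="distance")["editDistance"]
            assert align_to_target(a, t).score == expected

    def test_edlib_agrees_with_recursive_enumeration_on_tiny_pairs(self):
        # validates the oracle itself on exhaustively small inputs
        from itertools import product

        strings = [
            "".join(p) for n in range(5) for p in product("AC", repeat=n)
        ]
        for a in strings:
            for b in strings:
                if b:
                    assert (
                        edlib.align(a, b, task="distance")["editDistance"]
                        == brute_force_edit_distance(a, b)
                    )


class TestClassification:
    def test_identity_counts(self, nine_mer):
        ec = classify_errors(align_to_target(nine_mer, nine_mer), nine_mer, nine_mer)
        assert (ec.n_correct, ec.n_del, ec.n_ins, ec.n_sub) == (9, 0, 0, 0)

    def test_deletion_counts(self, nine_mer):
        ec = classify_errors(align_to_target("GCTGCT", nine_mer), nine_mer, "GCTGCT")
        assert ec.n_del == 3 and ec.n_correct == 6

    def test_insertion_classified(self):
        target, payload = "GCTCT", "GCATCT"
        ec = classify_errors(align_to_target(payload, target), target, payload)
        assert ec.n_ins == 1 and ec.n_correct == 5 and ec.n_del == 0 and ec.n_sub == 0

    @settings(derandomize=True, max_examples=150)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=10),
        st.text(alphabet="ACGT", max_size=12),
    )
    def test_conservation_per_read(self, target, payload):
        ec = classify_errors(align_to_target(payload, target), target, payload)
        assert ec.n_correct + ec.n_del + ec.n_sub == len(target)
        assert ec.n_correct + ec.n_sub + ec.n_ins == len(payload)


class TestMetrics:
    def test_all_correct_population(self, nine_mer):
        m = compute_metrics([nine_mer] * 50, nine_mer)
        assert m.full_length_yield == 1.0
        assert m.stepwise_yield == 1.0
        assert m.error_rate_del == m.error_rate_ins == m.error_rate_sub == 0.0

    @pytest.mark.parametrize(
        "y_total,r,expected_pct",
        [
            (0.7583, 9, 96.97),
            (0.9961, 3, 99.87),
            (0.8818, 3, 95.89),
            (0.1435, 60, 96.82),
        ],
    )
    def test_stepwise_yield_pairings(self, y_total, r, expected_pct):
        assert round(100 * stepwise_yield(y_total, r), 2) == expected_pct

    def test_metrics_from_constructed_population(self, nine_mer):
        # 7583 exact + 2417 single-deletion payloads: Y_total = 0.7583 exactly
        payloads = [nine_mer] * 7583 + [nine_mer[1:]] * 2417
        m = compute_metrics(payloads, nine_mer)
        assert m.full_length_yield == pytest.approx(0.7583)
        assert round(100 * m.stepwise_yield, 2) == 96.97
        assert m.N_del == 2417

    def test_conservation_invariant(self, nine_mer):
        run = SimulationRun(
            nine_mer, 2000, seed=13, model=ErrorModel(p_del=0.05, p_sub=0.03, p_ins=0.02)
        )
        payloads = [r.payload for r in simulate_run(run)]
        m = compute_metrics(payloads, nine_mer)
        assert m.N_right + m.N_del + m.N_sub == m.n_reads_extracted * m.r

    def test_yield_algebra(self, nine_mer):
        payloads = [nine_mer] * 700 + [nine_mer[:-1]] * 300
        m = compute_metrics(payloads, nine_mer)
        assert m.stepwise_yield ** m.r == pytest.approx(m.full_length_yield, rel=1e-12)

    def test_empty_population_rejected(self, nine_mer):
        with pytest.raises(ValueError):
            compute_metrics([], nine_mer)

    def test_deletion_rate_recovery(self, nine_mer):
        p_del, n = 0.0305, 20000
        run = SimulationRun(nine_mer, n, seed=17, model=ErrorModel(p_del=p_del))
        payloads = [r.payload for r in simulate_run(run)]
        m = compute_metrics(payloads, nine_mer)
        se = math.sqrt(p_del * (1 - p_del) / (n * 9))
        assert abs(m.error_rate_del - p_del) <= 3 * se


class TestPerPositionProfile:
    def test_error_free_reads_have_unit_target_frequency(self, nine_mer):
        df = per_position_profile([nine_mer] * 20, nine_mer)
        for k, base in enumerate(nine_mer, start=1):
            assert df.loc[k, base] == 1.0
            assert df.loc[k, "deleted"] == 0.0

    def test_rows_sum_to_one(self, nine_mer):
        run = SimulationRun(nine_mer, 1000, seed=23, model=ErrorModel(p_del=0.05))
        df = per_position_profile([r.payload for r in simulate_run(run)], nine_mer)
        sums = df[["A", "C", "G", "T", "deleted"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_deleted_fraction_estimates_per_cycle_rate(self, nine_mer):
        p_del, n = 0.0305, 20000
        run = SimulationRun(nine_mer, n, seed=29, model=ErrorModel(p_del=p_del))
        df = per_position_profile([r.payload for r in simulate_run(run)], nine_mer)
        se = math.sqrt(p_del * (1 - p_del) / n)
        # conditional screen: each surviving read deletes at the position w.p. p_del
        for k in df.index:
            assert abs(df.loc[k, "deleted"] - p_del) <= 4 * se
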