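import numpy as np
import pytest

from norkit.finishing import (
    MergeError,
    VectorAbsentError,
    finish_assembly,
    merge_inserts,
    trim_circular_overlap,
)
from norkit.restriction import ECORV
from norkit.seq import revcomp, rotate
from norkit.synth import build_nor, simulate_clone
from conftest import scaled_spec, random_seq


class TestTrimCircularOverlap:
    def test_terminal_repeat_removed(self):
        t, removed = trim_circular_overlap("ACGTTGCAGGACGTT", min_overlap=3, max_divergence=0)
        assert removed == 5 and t == "ACGTTGCAGG"

    def test_no_terminal_repeat_unchanged(self, rng):
        s = random_seq(rng, 500)
        t, removed = trim_circular_overlap(s, min_overlap=20)
        assert (t, removed) == (s, 0) or s[:removed] == s[len(s) - removed:]

    def test_whole_sequence_self_identity_not_treated_as_overlap(self):
        s = "ACGTACGT"  # suffix of length 4 equals prefix, but 4 == len/2
        assert trim_circular_overlap(s, min_overlap=3, max_divergence=0) == (s, 0)

    def test_matches_brute_force_longest_suffix_prefix(self, rng):
        from oracles import longest_suffix_prefix

        for _ in range(200):
            core = random_seq(rng, int(rng.integers(30, 120)))
            dup = int(rng.integers(0, len(core) // 2))
            s = core + core[:dup]
            expect = longest_suffix_prefix(s, 5, 0.0)
            t, removed = trim_circular_overlap(s, min_overlap=5, max_divergence=0.0)
            assert removed == expect
            assert t == s[: len(s) - removed]

    def test_idempotent(self, rng):
        core = random_seq(rng, 300)
        s = core + core[:80]
        t, removed = trim_circular_overlap(s, min_overlap=50)
        assert removed == 80
        t2, removed2 = trim_circular_overlap(t, min_overlap=50)
        assert removed2 == 0 and t2 == t

    def test_tolerates_divergence_in_overlap(self, rng):
        core = random_seq(rng, 400)
        dup = list(core[:100])
        dup[50] = "A" if dup[50] != "A" else "C"
        s = core + "".join(dup)
        _, removed = trim_circular_overlap(s, min_overlap=50, max_divergence=0.02)
        assert removed == 100


class TestFinishAssembly:
    def test_linear_vector_at_start_no_overlap(self, rng):
        vector = random_seq(rng, 200)
        insert = random_seq(rng, 800)
        fc = finish_assembly(vector + insert, vector)
        assert fc.insert == insert
        assert fc.circular_overlap_removed == 0
        assert fc.vector_interval_removed == (1, 200)

    def test_vector_absent_errors(self, rng):
        with pytest.raises(VectorAbsentError, match="vector absent"):
            finish_assembly(random_seq(rng, 1000), random_seq(rng, 200))

    def test_missing_hook_flags_clone_invalid(self, rng):
        vector = random_seq(rng, 200)
        insert = random_seq(rng, 800)
        fc = finish_assembly(vector + insert, vector,
                             hooks={"h5": insert[:50], "bogus": "G" * 60})
        assert fc.hooks_found == {"h5": True, "bogus": False}
        assert not fc.valid

    def test_vector_found_despite_consensus_errors(self, rng):
        vector = random_seq(rng, 1000)
        noisy = list(vector)
        for i in range(0, 1000, 67):  # ~1.5% scattered errors
            noisy[i] = "A" if noisy[i] != "A" else "C"
        insert = random_seq(rng, 2000)
        fc = finish_assembly("".join(noisy) + insert, vector)
        assert fc.insert == insert

    def test_roundtrip_recovers_truth_insert_over_random_clones(self, rng):
        nor = build_nor(scaled_spec(seed=51))
        vector = random_seq(rng, 3000)
        ct0 = simulate_clone(nor, ECORV, vector, rotation=0)
        circle_len = len(vector) + len(ct0.insert)
        for _ in range(30):
            rot = int(rng.integers(0, circle_len))
            ov = 0 if rng.random() < 0.25 else int(rng.integers(100, 1000))
            ct = simulate_clone(nor, ECORV, vector, rotation=rot, circular_overlap=ov)
            fc = finish_assembly(ct.emitted, vector,
                                 hooks={"h5": ct.hook5, "h3": ct.hook3})
            assert fc.insert == ct.insert
            assert fc.valid
            assert fc.circular_overlap_removed == ov

    def test_finishing_is_deterministic_and_stable(self, rng):
        nor = build_nor(scaled_spec(seed=52))
        vector = random_seq(rng, 2000)
        ct = simulate_clone(nor, ECORV, vector, rotation=777, circular_overlap=400)
        a = finish_assembly(ct.emitted, vector)
        b = finish_assembly(ct.emitted, vector)
        assert a.insert == b.insert
        # re-trimming the finished insert changes nothing
        assert trim_circular_overlap(a.insert)[1] == 0


class TestMergeInserts:
    def test_known_example(self):
        m = merge_inserts("ACGTACGT", "ACGTTTTT", min_overlap=4)
        assert m.contig == "ACGTACGTTTTT"
        assert m.overlap_length == 4 and m.mismatches_in_overlap == 0
        assert len(m.contig) == 8 + 8 - 4

    def test_identical_inputs_rejected_by_degenerate_guard(self, rng):
        # a full-length self-match is never an overlap: only proper terminal
        # overlaps (shorter than either input) qualify
        a = random_seq(rng, 300)
        with pytest.raises(MergeError):
            merge_inserts(a, a, min_overlap=50)

    def test_reverse_strand_overlap_found(self, rng):
        a = random_seq(rng, 600)
        b_forward = a[-150:] + random_seq(rng, 400)
        m = merge_inserts(a, revcomp(b_forward), min_overlap=100)
        assert m.overlap_length == 150
        assert m.contig == a + b_forward[150:]
        assert "revcomp" in m.orientation

    def test_order_swap_handled(self, rng):
        b = random_seq(rng, 600)
        a = b[-200:] + random_seq(rng, 300)
        m = merge_inserts(a, b, min_overlap=100, id_a="A", id_b="B")
        assert m.orientation == "B+A"
        assert m.contig == b + a[200:]

    def test_length_conservation_on_random_overlaps(self, rng):
        from oracles import best_suffix_prefix_overlap

        for _ in range(50):
            left = random_seq(rng, int(rng.integers(200, 600)))
            ov = int(rng.integers(50, min(150, len(left))))
            right = left[-ov:] + random_seq(rng, int(rng.integers(100, 400)))
            m = merge_inserts(left, right, min_overlap=40)
            assert len(m.contig) == len(left) + len(right) - m.overlap_length
            oracle = best_suffix_prefix_overlap(left, right, 40, 0.01)
            assert m.overlap_length == oracle[0]

    def test_no_overlap_reports_best_subthreshold_candidate(self, rng):
        a, b = random_seq(rng, 300), random_seq(rng, 300)
        with pytest.raises(MergeError) as exc:
            merge_inserts(a, b, min_overlap=50)
        # a best near-miss may or may not exist for pure random sequences
        assert "no qualifying terminal overlap" in str(exc.value)

    def test_merged_contig_reproduces_nor_slice(self, rng):
        nor = build_nor(scaled_spec(seed=61))
        vector = random_seq(rng, 2500)
        ct = simulate_clone(nor, ECORV, vector, rotation=4242, circular_overlap=300)
        fc = finish_assembly(ct.emitted, vector)
        designed_overlap = 800
        pj_clone = nor.sequence[: ct.fragment[0] - 1 + designed_overlap]
        m = merge_inserts(pj_clone, fc.insert, min_overlap=100,
                          id_a="PJ", id_b="array")
        assert m.overlap_length == designed_overlap
        assert m.contig == nor.sequence[: ct.fragment[1]]
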