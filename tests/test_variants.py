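import itertools

import numpy as np
import pytest

from norkit.align import align_units
from norkit.synth import mutate_unit
from norkit.variants import (
    VariantRecord,
    call_variants,
    classify_sharing,
    left_normalize,
    map_to_features,
    pairwise_divergence,
    region_density,
)
from conftest import random_seq
from oracles import feature_overlap_brute


class TestLeftNormalize:
    def test_snv_unchanged(self):
        assert left_normalize(5, "A", "G", "CCCCACCC") == (5, "A", "G")

    def test_homopolymer_deletion_shifts_leftmost(self):
        #      123456789
        ref = "CTAAAAGGC"
        # raw deletion of the A at position 6 == deletion of any A in the run
        assert left_normalize(6, "A", "", ref) == (2, "TA", "T")

    def test_insertion_anchored_on_preceding_base(self):
        ref = "ACGTACGT"
        # TT inserted before position 5 extends the T at position 4; the
        # leftmost equivalent placement anchors on the G at position 3
        assert left_normalize(5, "", "TT", ref) == (3, "G", "GTT")
        # no homopolymer context: anchor directly on the preceding base
        assert left_normalize(5, "", "CC", ref) == (4, "T", "TCC")

    def test_event_at_position_one_anchors_right(self):
        ref = "AAGT"
        pos, r, a = left_normalize(1, "A", "", ref)
        assert pos == 1 and len(r) == len(a) + 1


class TestCallVariants:
    def test_all_match_alignment_yields_no_variants(self, rng):
        s = random_seq(rng, 500)
        pair = align_units(s, s)
        assert call_variants(pair, s, s) == []

    def test_position_outside_annotation_labelled_unannotated(self, rng):
        ref = random_seq(rng, 200)
        alt = ref[:99] + ("A" if ref[99] != "A" else "C") + ref[100:]
        pair = align_units(ref, alt, band=16)
        recs = call_variants(pair, ref, alt, annotation=[("18S", 1, 50)])
        assert len(recs) == 1 and recs[0].region == "unannotated"

    def test_homopolymer_deletion_reported_at_leftmost_placement(self):
        ref = "GGCC" + "A" * 8 + "GGCC" + "TTTT"
        alt = "GGCC" + "A" * 7 + "GGCC" + "TTTT"
        pair = align_units(ref, alt, band=8)
        (rec,) = call_variants(pair, ref, alt)
        # every placement of the single-A deletion is equivalent; the leftmost
        # anchored representation starts at the base before the A-run
        assert (rec.pos, rec.ref, rec.alt) == (4, "CA", "C")
        assert rec.vtype == "DEL"

    def test_truth_recovery_on_simulated_units(self, rng):
        annot = [("18S", 1, 1000), ("IGS", 1001, 2000)]
        rates = {"18S": 7.5, "IGS": 7.5}
        tp = fp = fn = 0
        for k in range(20):
            ref = random_seq(rng, 2000)
            mut, truth = mutate_unit(ref, annot, rates, 5000 + k)
            pair = align_units(ref, mut, band=64)
            called = call_variants(pair, ref, mut, annot)
            truth_keys = {r.key for r in truth}
            called_keys = {r.key for r in called}
            tp += len(truth_keys & called_keys)
            fp += len(called_keys - truth_keys)
            fn += len(truth_keys - called_keys)
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.95 and recall >= 0.95


class TestPairwiseDivergence:
    def test_identical_units_mean_and_se_zero(self, rng):
        s = random_seq(rng, 800)
        d = pairwise_divergence({"u1": s, "u2": s, "u3": s})
        assert d.mean == 0.0 and d.sem == 0.0
        assert len(d.pairs) == 3  # C(3,2)

    def test_mean_and_sem_closed_form(self, rng):
        # engineer pairwise counts {1,2,3}: B = A + 1 SNV, C = A + 2 other SNVs
        a = random_seq(rng, 2000)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        b = a[:500] + flip[a[500]] + a[501:]
        c = a[:1000] + flip[a[1000]] + a[1001:1500] + flip[a[1500]] + a[1501:]
        d = pairwise_divergence({"a": a, "b": b, "c": c})
        counts = sorted(d.pairs["n_variants"])
        assert counts == [1, 2, 3]
        assert d.mean == pytest.approx(2.0)
        assert d.sem == pytest.approx(0.5774, abs=1e-4)

    def test_single_unit_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            d = pairwise_divergence({"only": "ACGTACGTAC"})
        assert d.pairs.empty

    def test_count_invariant_under_dict_order(self, rng):
        a = random_seq(rng, 1500)
        b = a[:700] + ("A" if a[700] != "A" else "G") + a[701:]
        d1 = pairwise_divergence({"a": a, "b": b})
        d2 = pairwise_divergence({"b": b, "a": a})
        assert list(d1.pairs["n_variants"]) == list(d2.pairs["n_variants"]) == [1]


class TestClassifySharing:
    GROUPS = {"u1": "chr22", "u2": "chr22", "u3": "chr21", "u4": "chr21"}

    @staticmethod
    def rec(unit, pos):
        return VariantRecord(unit, pos, "SNV", "A", "G")

    def test_universal_shared_unique_partition(self):
        per_unit = {
            "u1": [self.rec("u1", 10), self.rec("u1", 20)],
            "u2": [self.rec("u2", 10), self.rec("u2", 20)],
            "u3": [self.rec("u3", 10)],
            "u4": [self.rec("u4", 10), self.rec("u4", 30)],
        }
        t = classify_sharing(per_unit, self.GROUPS)
        cls = dict(zip(t.table["pos"], t.table["cls"]))
        assert cls == {10: "universal", 20: "shared", 30: "unique"}
        assert sum(t.counts().values()) == len(t.table)

    def test_matches_brute_force_on_random_memberships(self, rng):
        units = [f"u{i}" for i in range(8)]
        groups = {u: ("chr22" if i < 4 else "chr21") for i, u in enumerate(units)}
        all_groups = set(groups.values())
        for trial in range(50):
            per_unit = {u: [] for u in units}
            truth = {}
            for pos in range(1, 15):
                carriers = [u for u in units if rng.random() < 0.3]
                if not carriers:
                    continue
                for u in carriers:
                    per_unit[u].append(self.rec(u, pos))
                covered = {groups[u] for u in carriers}
                if len(carriers) == 1:
                    truth[pos] = "unique"
                elif covered == all_groups:
                    truth[pos] = "universal"
                else:
                    truth[pos] = "shared"
            t = classify_sharing(per_unit, groups)
            assert dict(zip(t.table["pos"], t.table["cls"])) == truth

    def test_unknown_unit_group_rejected(self):
        with pytest.raises(ValueError, match="without a chromosome group"):
            classify_sharing({"ux": []}, {"other": "chr22"})


class TestRegionDensity:
    ANNOT = [("18S", 1, 2000), ("IGS", 2001, 6000)]

    def test_density_arithmetic(self):
        variants = [VariantRecord("u", p, "SNV", "A", "G", "18S") for p in range(1, 11)]
        df = region_density(variants, self.ANNOT)
        row = df[df["region"] == "18S"].iloc[0]
        assert row["per_kb"] == pytest.approx(5.0)
        assert df[df["region"] == "IGS"].iloc[0]["per_kb"] == 0.0

    def test_ratio_row_present(self):
        variants = [VariantRecord("u", 100, "SNV", "A", "G", "18S"),
                    VariantRecord("u", 3000, "SNV", "A", "G", "IGS"),
                    VariantRecord("u", 4000, "SNV", "A", "G", "IGS")]
        df = region_density(variants, self.ANNOT)
        ratio = df.loc[df["region"] == "IGS/transcribed_ratio", "per_kb"].iloc[0]
        assert ratio == pytest.approx((2 / 4) / (1 / 2))

    def test_zero_length_region_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero length"):
            df = region_density([], [("18S", 1, 1000), ("5.8S", 1001, 1000)])
        assert "5.8S" not in set(df["region"])


class TestMapToFeatures:
    FEATURES = [("CTCF", 100, 120), ("SalT1", 300, 310)]

    def test_variant_inside_feature_distance_zero(self):
        v = [VariantRecord("u", 110, "SNV", "A", "G")]
        df = map_to_features(v, self.FEATURES)
        assert list(df["distance"]) == [0]

    def test_upstream_proximity_negative_distance(self):
        v = [VariantRecord("u", 70, "SNV", "A", "G")]
        df = map_to_features(v, self.FEATURES, proximity=50)
        assert list(df["distance"]) == [-30]
        assert map_to_features(v, self.FEATURES, proximity=20).empty

    def test_matches_brute_force_scan(self, rng):
        features = []
        for i in range(30):
            s = int(rng.integers(1, 5000))
            features.append((f"f{i}", s, s + int(rng.integers(0, 200))))
        for _ in range(1000):
            pos = int(rng.integers(1, 5200))
            v = [VariantRecord("u", pos, "SNV", "A", "G")]
            df = map_to_features(v, features, proximity=50)
            got = sorted(zip(df["feature"], df["distance"]))
            assert got == sorted(feature_overlap_brute(pos, features, 50))

    def test_malformed_interval_reports_line(self):
        with pytest.raises(ValueError, match="line 2"):
            map_to_features([], [("ok", 1, 10), ("bad", 20, 5)])
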