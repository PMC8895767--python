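"""Ensemble calling: task distributions, averaging, decisions, records."""

import numpy as np
import pytest

from capcall.io import GenomicRegion, ReferenceSequence
from capcall.ensemble import (
    CallerConfig,
    GT21_CLASSES,
    GT21_INDEX,
    N_LENGTH_BINS,
    NaiveDiploidModel,
    TaskProbabilities,
    ZYGOSITY_CLASSES,
    average_probabilities,
    bin_to_length,
    call_targets,
    decide,
    decision_to_record,
    gt21_class,
    length_to_bin,
    naive_model,
)
from capcall.resample import Observation, PileupColumn

from conftest import make_column, make_read


def make_probs(gt21="AA", zygosity="hom_ref", d1=0, d2=0, peak=0.9):
    """Near-one-hot task distributions peaked at the given classes."""
    def vec(size, idx):
        v = np.full(size, (1.0 - peak) / (size - 1))
        v[idx] = peak
        return v

    return TaskProbabilities(
        gt21=vec(len(GT21_CLASSES), GT21_INDEX[gt21]),
        zygosity=vec(len(ZYGOSITY_CLASSES), ZYGOSITY_CLASSES.index(zygosity)),
        len1=vec(N_LENGTH_BINS, length_to_bin(d1)),
        len2=vec(N_LENGTH_BINS, length_to_bin(d2)),
    )


class TestEncodings:
    def test_length_bins_roundtrip_and_clamp(self):
        for d in range(-16, 17):
            assert bin_to_length(length_to_bin(d)) == d
        assert length_to_bin(-40) == length_to_bin(-16) == 0
        assert length_to_bin(40) == length_to_bin(16) == N_LENGTH_BINS - 1

    def test_gt21_canonical_unordered(self):
        assert gt21_class("C", "A") == "AC"
        assert gt21_class("A", "C") == "AC"
        assert gt21_class("I", "D") == "ID"
        assert gt21_class("G", "G") == "GG"
        with pytest.raises(ValueError):
            gt21_class("A", "X")

    def test_gt21_class_list_is_complete_and_unique(self):
        assert len(GT21_CLASSES) == 21
        assert len(set(GT21_CLASSES)) == 21

    def test_validate_rejects_bad_distributions(self):
        tp = make_probs()
        tp.gt21 = tp.gt21 * 2
        with pytest.raises(ValueError, match="sums"):
            tp.validate()
        tp = make_probs()
        tp.len1 = np.zeros(5)
        with pytest.raises(ValueError, match="shape"):
            tp.validate()


class TestNaiveDiploidModel:
    def test_hom_ref_column(self):
        col = make_column({"A": 50}, ref_base="A", qual=20)
        tp = naive_model(col.observations, "A")
        assert np.argmax(tp.zygosity) == 0
        assert GT21_CLASSES[np.argmax(tp.gt21)] == "AA"
        assert np.argmax(tp.len1) == length_to_bin(0)

    def test_balanced_het_snv(self):
        col = make_column({"A": 25, "C": 25}, ref_base="A", qual=20)
        tp = naive_model(col.observations, "A")
        assert ZYGOSITY_CLASSES[np.argmax(tp.zygosity)] == "het_alt"
        assert GT21_CLASSES[np.argmax(tp.gt21)] == "AC"

    def test_hom_alt_snv(self):
        col = make_column({"T": 40}, ref_base="A", qual=20)
        tp = naive_model(col.observations, "A")
        assert ZYGOSITY_CLASSES[np.argmax(tp.zygosity)] == "hom_alt"
        assert GT21_CLASSES[np.argmax(tp.gt21)] == "TT"

    def test_het_insertion_length_mass(self):
        col = make_column({"A": 20}, ref_base="A", qual=20, ins=[("TTT", 20)])
        tp = naive_model(col.observations, "A")
        assert ZYGOSITY_CLASSES[np.argmax(tp.zygosity)] == "het_alt"
        assert GT21_CLASSES[np.argmax(tp.gt21)] == "AI"
        # sorted deltas of (A, +3) are (0, +3)
        assert bin_to_length(int(np.argmax(tp.len1))) == 0
        assert bin_to_length(int(np.argmax(tp.len2))) == 3

    def test_het_deletion_length_mass(self):
        col = make_column({"G": 20}, ref_base="G", qual=20, dels=[(2, 20)])
        tp = naive_model(col.observations, "G")
        assert GT21_CLASSES[np.argmax(tp.gt21)] == "GD"
        assert bin_to_length(int(np.argmax(tp.len1))) == -2
        assert bin_to_length(int(np.argmax(tp.len2))) == 0

    def test_error_rate_floor(self):
        """Qual 40 observations are floored to the error-rate prior, so a
        lone dissenting base cannot overwhelm 30 reference reads."""
        col = make_column({"A": 30, "C": 1}, ref_base="A", qual=40)
        tp = NaiveDiploidModel(error_rate_prior=0.05)(col.observations, "A")
        assert np.argmax(tp.zygosity) == 0

    def test_outputs_are_valid_distributions(self, rng):
        for _ in range(20):
            obs = [
                Observation(f"r{i}", "base", "ACGT"[rng.integers(4)],
                            int(rng.integers(3, 41)))
                for i in range(int(rng.integers(1, 40)))
            ]
            naive_model(obs, "A").validate()

    def test_empty_partition_raises(self):
        with pytest.raises(ValueError):
            naive_model([], "A")


class TestAveraging:
    def test_mean_matches_manual(self, rng):
        sets = [
            make_probs(peak=float(rng.uniform(0.3, 0.95))) for _ in range(7)
        ]
        avg = average_probabilities(sets)
        for task in ("gt21", "zygosity", "len1", "len2"):
            manual = sum(getattr(tp, task) for tp in sets) / len(sets)
            np.testing.assert_allclose(getattr(avg, task), manual, atol=1e-12)

    def test_permutation_invariant_and_idempotent(self):
        a = make_probs("AC", "het_alt", peak=0.7)
        b = make_probs("GG", "hom_alt", peak=0.8)
        ab = average_probabilities([a, b])
        ba = average_probabilities([b, a])
        np.testing.assert_array_equal(ab.gt21, ba.gt21)
        solo = average_probabilities([a])
        np.testing.assert_array_equal(solo.zygosity, a.zygosity)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            average_probabilities([])


class TestDecide:
    def test_hom_ref_is_not_a_variant(self):
        col = make_column({"A": 10}, ref_base="A")
        d = decide(make_probs("AA", "hom_ref"), "A", col)
        assert not d.is_variant and d.genotype == "0/0"

    def test_het_snv(self):
        col = make_column({"A": 10, "C": 10}, ref_base="A")
        d = decide(make_probs("AC", "het_alt"), "A", col)
        assert d.is_variant and d.genotype == "0/1"
        assert d.alt_descriptors == (("snv", "C"),)
        assert not d.conflict

    def test_hom_alt_snv(self):
        col = make_column({"T": 10}, ref_base="A")
        d = decide(make_probs("TT", "hom_alt"), "A", col)
        assert d.genotype == "1/1" and d.alt_descriptors == (("snv", "T"),)

    def test_het_multi_two_alts(self):
        col = make_column({"C": 10, "G": 10}, ref_base="A")
        d = decide(make_probs("CG", "het_multi"), "A", col)
        assert d.genotype == "1/2"
        assert set(d.alt_descriptors) == {("snv", "C"), ("snv", "G")}

    def test_insertion_realized_by_length(self):
        col = make_column({"A": 10}, ref_base="A",
                          ins=[("TT", 8), ("GGG", 2)])
        d = decide(make_probs("AI", "het_alt", d1=0, d2=3), "A", col)
        assert d.alt_descriptors == (("ins", "GGG"),)
        assert not d.conflict

    def test_insertion_fallback_flags_conflict(self):
        col = make_column({"A": 10}, ref_base="A", ins=[("TT", 8)])
        d = decide(make_probs("AI", "het_alt", d1=0, d2=5), "A", col)
        assert d.alt_descriptors == (("ins", "TT"),)
        assert d.conflict

    def test_unrealizable_indel_falls_back_to_next_class(self):
        """gt21 argmax says insertion but the column holds none: the next
        best class with a realizable alt is used, flagged as a conflict."""
        tp = make_probs("AI", "het_alt", d1=0, d2=2, peak=0.6)
        # boost AC to be the runner-up
        tp.gt21[GT21_INDEX["AC"]] = 0.3
        tp.gt21 /= tp.gt21.sum()
        col = make_column({"A": 10, "C": 5}, ref_base="A")
        d = decide(tp, "A", col)
        assert d.is_variant and d.alt_descriptors == (("snv", "C"),)
        assert d.conflict

    def test_het_multi_downgrades_with_single_alt(self):
        col = make_column({"C": 10}, ref_base="A")
        d = decide(make_probs("CC", "het_multi"), "A", col)
        assert d.genotype == "0/1" and d.conflict

    def test_qual_formula_snv(self):
        col = make_column({"A": 10, "C": 10}, ref_base="A")
        tp = make_probs("AC", "het_alt", peak=0.9)
        d = decide(tp, "A", col)
        worst = min(tp.zygosity.max(), tp.gt21.max())
        assert d.qual == pytest.approx(-10 * np.log10(1 - worst))

    def test_qual_consults_length_tasks_for_indels(self):
        col = make_column({"A": 10}, ref_base="A", dels=[(2, 8)])
        tp = make_probs("AD", "het_alt", d1=-2, d2=0, peak=0.9)
        tp.len1 = np.full(N_LENGTH_BINS, 1.0 / N_LENGTH_BINS)
        d = decide(tp, "A", col)
        assert d.qual == pytest.approx(
            -10 * np.log10(1 - 1.0 / N_LENGTH_BINS)
        )

    def test_qual_capped_at_99(self):
        col = make_column({"C": 10}, ref_base="A")
        d = decide(make_probs("CC", "hom_alt", peak=1.0 - 1e-13), "A", col)
        assert d.qual == 99.0


class TestDecisionToRecord:
    REF = ReferenceSequence("chr1", "ACGTACGTACGTACGTACGT")

    def test_snv_record(self):
        col = make_column({"C": 10}, ref_base="A", pos=5)  # ref[4] == "A"
        d = decide(make_probs("CC", "hom_alt"), "A", col)
        rec = decision_to_record(d, col, self.REF)
        assert (rec.pos, rec.ref, rec.alts, rec.genotype) == (5, "A", ("C",), (1, 1))

    def test_insertion_record(self):
        col = make_column({"A": 10}, ref_base="A", pos=5, ins=[("TT", 8)])
        d = decide(make_probs("AI", "het_alt", d1=0, d2=2), "A", col)
        rec = decision_to_record(d, col, self.REF)
        assert (rec.pos, rec.ref, rec.alts) == (5, "A", ("ATT",))

    def test_deletion_anchored_one_base_left(self):
        # deletion of ref[5:7] ("CG") observed at column pos 6 (ref_base C);
        # anchor is pos 5 (A): REF "ACG", ALT "A"
        obs = [Observation(f"d{i}", "del", 2, 20, event_start=True)
               for i in range(8)]
        obs += [Observation(f"b{i}", "base", "C", 20) for i in range(8)]
        col = PileupColumn("chr1", 6, "C", obs)
        d = decide(make_probs("CD", "het_alt", d1=-2, d2=0), "C", col)
        rec = decision_to_record(d, col, self.REF, min_del_support=4)
        assert (rec.pos, rec.ref, rec.alts, rec.genotype) == (5, "ACG", ("A",), (0, 1))

    def test_deletion_without_event_start_support_suppressed(self):
        # interior of a longer deletion: observations carry event_start=False
        obs = [Observation(f"d{i}", "del", 2, 20, event_start=False)
               for i in range(8)]
        obs += [Observation(f"b{i}", "base", "C", 20) for i in range(8)]
        col = PileupColumn("chr1", 6, "C", obs)
        d = decide(make_probs("CD", "het_alt", d1=-2, d2=0), "C", col)
        assert decision_to_record(d, col, self.REF, min_del_support=4) is None

    def test_non_variant_returns_none(self):
        col = make_column({"A": 10}, ref_base="A", pos=5)
        d = decide(make_probs("AA", "hom_ref"), "A", col)
        assert decision_to_record(d, col, self.REF) is None


class TestCallTargets:
    def _scenario(self, alt_fraction):
        """40 reads over ACGT×10; a fraction carry C at 0-based 10."""
        ref = ReferenceSequence("chr1", "ACGTACGTAC" * 4)
        regions = [GenomicRegion("chr1", 0, 40)]
        reads = []
        n_alt = int(40 * alt_fraction)
        for i in range(40):
            seq = list(ref.seq[2:38])
            if i < n_alt:
                seq[8] = "C"  # 0-based ref position 10
            s = "".join(seq)
            reads.append(make_read(f"r{i}", "chr1", 2, [("M", 36)], s,
                                   [25] * 36))
        return ref, regions, reads

    def test_het_snv_called(self):
        ref, regions, reads = self._scenario(0.5)
        records = call_targets(reads, ref, regions)
        assert len(records) == 1
        rec = records[0]
        assert (rec.pos, rec.ref, rec.alts, rec.genotype) == (11, "A", ("C",), (0, 1))
        assert rec.filter == "PASS"

    def test_below_candidate_threshold_not_called(self):
        ref, regions, reads = self._scenario(0.05)  # 2 alt reads < 4
        assert call_targets(reads, ref, regions) == []

    def test_clean_data_produces_no_calls(self, clean_dataset):
        ds = clean_dataset
        records = call_targets(ds.reads, ds.reference, ds.regions)
        assert records == []

    def test_deterministic(self, small_dataset):
        ds = small_dataset
        a = call_targets(ds.reads, ds.reference, ds.regions)
        b = call_targets(ds.reads, ds.reference, ds.regions)
        assert a == b
        assert len(a) > 0

    def test_requires_a_model(self):
        ref, regions, reads = self._scenario(0.5)
        with pytest.raises(ValueError):
            call_targets(reads, ref, regions, models=[])
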