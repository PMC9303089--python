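from __future__ import annotations

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sequence
from kspec.evaluation import (
    Confusion,
    apply_tef_edits,
    classify_by_alignment,
    classify_corrections,
    error_context_profile,
    evaluate,
    metrics,
)
from kspec.io_formats import TefEdit, TefRecord


def sub(pos, observed, true):
    return TefEdit(pos, observed, true, "substitution")


class TestClassifyCorrections:
    def test_exact_correction_is_tp(self):
        truth = [TefRecord(0, (sub(4, "T", "G"),))]
        applied = [TefRecord(0, (sub(4, "T", "G"),))]
        conf = classify_corrections(truth, applied, [5])
        assert (conf.TP, conf.FP, conf.FN, conf.TN) == (1, 0, 0, 4)

    def test_missed_error_is_fn(self):
        truth = [TefRecord(0, (sub(4, "T", "G"),))]
        conf = classify_corrections(truth, [], [5])
        assert (conf.TP, conf.FP, conf.FN, conf.TN) == (0, 0, 1, 4)

    def test_wrong_replacement_fn_and_spurious_edit_fp(self):
        truth = [TefRecord(0, (sub(4, "T", "G"),))]
        applied = [TefRecord(0, (sub(1, "C", "A"), sub(4, "T", "A")))]
        conf = classify_corrections(truth, applied, [6])
        # wrong replacement at 4 counts FN only; edit at 1 is FP
        assert (conf.TP, conf.FP, conf.FN, conf.TN) == (0, 1, 1, 4)

    def test_mismatched_read_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_corrections([TefRecord(3, ())], [], [5])

    def test_position_beyond_read_rejected(self):
        truth = [TefRecord(0, (sub(7, "T", "G"),))]
        with pytest.raises(ValueError):
            classify_corrections(truth, [], [5])

    def test_indel_edits_rejected_in_positional_mode(self):
        truth = [TefRecord(0, (TefEdit(2, "-", "G", "deletion"),))]
        with pytest.raises(ValueError, match="alignment"):
            classify_corrections(truth, [], [5])

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_partition_and_gain_bound(self, data):
        r = random.Random(data.draw(st.integers(0, 10**6)))
        n_reads, length = 6, 30
        def random_records():
            records = []
            for idx in range(n_reads):
                positions = sorted(r.sample(range(length), r.randint(0, 4)))
                edits = []
                for p in positions:
                    observed = r.choice("ACGT")
                    true = r.choice([b for b in "ACGT" if b != observed])
                    edits.append(sub(p, observed, true))
                records.append(TefRecord(idx, tuple(edits)))
            return records

        truth, applied = random_records(), random_records()
        conf = classify_corrections(truth, applied, [length] * n_reads)
        assert conf.total == n_reads * length
        assert conf.TP + conf.FN == sum(len(t.edits) for t in truth)
        result = metrics(conf)
        if "gain" not in result.undefined:
            assert result.gain <= result.recall + 1e-12

    def test_truth_as_applied_is_perfect(self):
        r = random.Random(5)
        truth = [
            TefRecord(0, (sub(3, "A", "C"), sub(9, "G", "T"))),
            TefRecord(1, (sub(0, "T", "A"),)),
        ]
        result = evaluate(truth, truth, [20, 20])
        assert result.confusion.FP == 0 and result.confusion.FN == 0
        assert result.gain == 1.0


class TestMetrics:
    def test_perfect_correction_gain_one(self):
        result = metrics(Confusion(TP=10, FP=0, FN=0, TN=90))
        assert result.gain == 1.0
        assert result.precision == result.recall == result.f_score == 1.0

    def test_negative_gain_when_more_harm_than_good(self):
        result = metrics(Confusion(TP=5, FP=10, FN=5, TN=0))
        assert result.gain == -0.5

    def test_direct_formula_evaluation(self):
        result = metrics(Confusion(TP=8, FP=2, FN=2, TN=88))
        assert result.precision == pytest.approx(0.8)
        assert result.recall == pytest.approx(0.8)
        assert result.f_score == pytest.approx(0.8)
        assert result.gain == pytest.approx(0.6)

    def test_undefined_flags_not_zero(self):
        result = metrics(Confusion(TP=0, FP=0, FN=0, TN=10))
        assert math.isnan(result.gain) and math.isnan(result.precision)
        assert result.undefined == {"gain", "recall", "precision", "f_score"}

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_f_score_between_precision_and_recall(self, tp, fp, fn):
        result = metrics(Confusion(tp, fp, fn, 100))
        if not result.undefined:
            lo = min(result.precision, result.recall)
            hi = max(result.precision, result.recall)
            assert lo - 1e-12 <= result.f_score <= hi + 1e-12
            assert result.gain <= result.recall + 1e-12


class TestAlignmentClassification:
    def test_substitution_fixed(self):
        conf = classify_by_alignment("ACGTT", "ACGTG", "ACGTG")
        assert (conf.TP, conf.FP, conf.FN, conf.TN) == (1, 0, 0, 4)

    def test_deletion_restored(self):
        true_read = "ACGTACGT"
        original = "ACGACGT"  # T at position 3 missing
        corrected = true_read
        conf = classify_by_alignment(original, corrected, true_read)
        assert conf.TP == 1 and conf.FP == 0 and conf.FN == 0

    def test_introduced_error_is_fp(self):
        conf = classify_by_alignment("ACGTG", "ACGAG", "ACGTG")
        assert conf.FP == 1 and conf.TP == 0


class TestApplyTefEdits:
    def test_round_trip_with_indels(self):
        true_seq = "ACGTACGT"
        observed = "ACCTACGGT"  # sub at 2 (G->C) and spurious G at 7
        edits = (sub(2, "C", "G"), TefEdit(7, "G", "-", "insertion"))
        assert apply_tef_edits(observed, edits) == true_seq


class TestContextProfile:
    def test_direct_indexing(self):
        truth = [TefRecord(0, (sub(2, "T", "G"),))]
        profile = error_context_profile("AAGTC", [(0, "+")], truth, flank=1, read_lengths=[5])
        assert profile.counts == {"AGT": 1}

    def test_zero_errors_background_only(self):
        profile = error_context_profile("AAGTC", [(0, "+")], [TefRecord(0, ())], 1, [5])
        assert not profile.counts
        assert sum(profile.background.values()) > 0

    def test_edge_errors_skipped_with_counter(self):
        truth = [TefRecord(0, (sub(0, "A", "C"),))]
        profile = error_context_profile("AAGTC", [(0, "+")], truth, flank=2, read_lengths=[5])
        assert profile.skipped == 1

    def test_reverse_strand_tuple_in_read_orientation(self):
        # read covers ref[0:5] on the minus strand; read position 2 maps to
        # ref position 2; tuple revcomp'd into read orientation
        truth = [TefRecord(0, (sub(2, "T", "C"),))]
        profile = error_context_profile("AAGTC", [(0, "-")], truth, 1, [5])
        assert profile.counts == {"ACT": 1}  # revcomp("AGT")

    def test_planted_after_g_bias_recovered(self):
        r = random.Random(10)
        reference = random_sequence(r, 4000)
        placements, truth = [], []
        read_len, flank = 50, 3
        idx = 0
        for start in range(0, 3900, 13):
            # plant an error only immediately after a G inside the read body
            for offset in range(flank, read_len - flank):
                if reference[start + offset - 1] == "G":
                    placements.append((start, "+"))
                    observed = r.choice([b for b in "ACGT" if b != reference[start + offset]])
                    truth.append(TefRecord(idx, (sub(offset, observed, reference[start + offset]),)))
                    idx += 1
                    break
        profile = error_context_profile(
            reference, placements, truth, flank, [read_len] * len(placements)
        )
        freqs = profile.preceding_base_frequencies()
        assert freqs["G"] == 1.0
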