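from __future__ import annotations

import random

import pytest

from conftest import make_spectrum
from kspec.correction import (
    CorrectionParams,
    EditCandidate,
    correct_dataset,
    correct_long_region,
    correct_read,
    correct_short_region,
    enumerate_candidates,
)
from kspec.error_regions import ErrorRegion
from kspec.io_formats import ReadRecord, TefEdit
from kspec.spectrum import build_spectrum
from kspec.io_formats import tef_line


@pytest.fixture
def acgtt_spectrum():
    """'ACGTT' carries an error at base 4; the true context is ACG-CGT-GTG."""
    return make_spectrum({"ACG": 10, "CGT": 10, "GTG": 10}, k=3)


class TestEnumerateCandidates:
    def test_single_surviving_substitution(self, acgtt_spectrum):
        region = ErrorRegion(0, 2, 2, "short")
        candidates = enumerate_candidates("ACGTT", region, acgtt_spectrum, t_er=2)
        assert [(c.position, c.edit_type, c.replacement) for c in candidates] == [
            (4, "substitution", "G")
        ]
        assert candidates[0].min_count == 10

    def test_unfixable_region_is_empty(self):
        spec = make_spectrum({"TTT": 9}, k=3)
        region = ErrorRegion(0, 0, 2, "short")
        assert enumerate_candidates("ACGTA", region, spec, t_er=2) == []

    def test_planted_deletion_recoverable_with_indels(self, backbone_reads):
        genome, reads = backbone_reads
        k = 15
        spec = build_spectrum(reads, k)
        # drop base 30 from a 60 bp fragment of the backbone
        fragment = genome[:60]
        damaged = fragment[:30] + fragment[31:]
        region = ErrorRegion(0, 30 - k + 1, 30, "short")
        candidates = enumerate_candidates(damaged, region, spec, t_er=1, allow_indels=True)
        restoring = [
            c
            for c in candidates
            if c.edit_type == "insertion" and c.replacement == fragment[30]
        ]
        assert restoring
        # exhaustive single-edit oracle: no substitution can beat restoring
        # the deleted base, because only the insertion recreates the backbone
        best = candidates[0]
        assert best.edit_type == "insertion"
        assert best.position in (30 - 1, 30, 30 + 1) or best.min_count >= 7


class TestShortRegion:
    def test_acgtt_corrected(self, acgtt_spectrum):
        region = ErrorRegion(0, 2, 2, "short")
        result = correct_short_region("ACGTT", region, acgtt_spectrum, t_er=2)
        assert result is not None
        sequence, edits = result
        assert sequence == "ACGTG"
        assert [(e.position, e.replacement) for e in edits] == [(4, "G")]

    def test_stale_solid_region_unchanged(self, acgtt_spectrum):
        region = ErrorRegion(0, 0, 1, "short")  # ACG, CGT both solid
        result = correct_short_region("ACGTG", region, acgtt_spectrum, t_er=2)
        assert result == ("ACGTG", [])

    def test_uncorrectable_returns_none(self):
        spec = make_spectrum({"TTT": 9}, k=3)
        region = ErrorRegion(0, 0, 2, "short")
        assert correct_short_region("ACGTA", region, spec, t_er=2) is None

    def test_substitution_preferred_over_indel_on_tie(self):
        sub = EditCandidate(4, "substitution", "G", 10, 20)
        dele = EditCandidate(4, "deletion", "", 10, 20)
        assert sorted([dele, sub], key=lambda c: c.sort_key)[0] is sub

    def test_tie_breaks_are_total_and_deterministic(self):
        a = EditCandidate(4, "substitution", "A", 10, 20)
        c = EditCandidate(4, "substitution", "C", 10, 20)
        left = EditCandidate(3, "substitution", "T", 10, 20)
        ranked = sorted([c, a, left], key=lambda x: x.sort_key)
        assert ranked == [left, a, c]  # position, then alphabetical


class TestLongRegion:
    def test_two_errors_one_long_region(self, backbone_reads):
        genome, reads = backbone_reads
        k = 15
        spec = build_spectrum(reads, k)
        fragment = genome[20:80]
        damaged = list(fragment)
        for pos in (30, 35):  # 5 bp apart -> one merged long weak run
            damaged[pos] = "ACGT"[("ACGT".index(damaged[pos]) + 1) % 4]
        damaged = "".join(damaged)
        region = ErrorRegion(0, 30 - k + 1, 35, "long")
        result = correct_long_region(damaged, region, spec, t_er=1)
        assert result is not None
        sequence, edits = result
        assert sequence == fragment
        assert len(edits) == 2

    def test_novel_sequence_uncorrectable(self):
        r = random.Random(3)
        spec = make_spectrum({"AAAA": 50}, k=4)
        seq = "".join(r.choice("ACGT") for _ in range(30))
        region = ErrorRegion(0, 0, 26, "long")
        assert correct_long_region(seq, region, spec, t_er=2) is None


class TestCorrectRead:
    def _params(self, **kw):
        return CorrectionParams(k=3, canonical=False, **kw)

    def test_all_solid_read_unchanged(self, acgtt_spectrum):
        read = ReadRecord("r", "ACGTG", "IIIII")
        outcome = correct_read(read, acgtt_spectrum, 2, self._params())
        assert outcome.status == "unchanged"
        assert outcome.applied_edits == []
        assert outcome.corrected_sequence == "ACGTG"

    def test_single_error_read_corrected(self, acgtt_spectrum):
        read = ReadRecord("r", "ACGTT", "IIIII")
        outcome = correct_read(read, acgtt_spectrum, 2, self._params())
        assert outcome.status == "corrected"
        assert outcome.corrected_sequence == "ACGTG"
        assert outcome.applied_edits == [TefEdit(4, "T", "G", "substitution")]
        assert outcome.corrected_qualities == "IIIII"

    def test_contaminant_uncorrectable_then_discarded(self):
        spec = make_spectrum({"AAA": 50}, k=3)
        read = ReadRecord("r", "CGTACGT", "IIIIIII")
        keep = correct_read(read, spec, 2, self._params())
        assert keep.status == "uncorrectable"
        drop = correct_read(read, spec, 2, self._params(discard_policy="drop"))
        assert drop.status == "discarded"

    def test_corrected_read_has_no_weak_kmers(self, acgtt_spectrum):
        from kspec.correction import _weak_starts

        outcome = correct_read(
            ReadRecord("r", "ACGTT", "IIIII"), acgtt_spectrum, 2, self._params()
        )
        assert outcome.status == "corrected"
        assert not _weak_starts(outcome.corrected_sequence, acgtt_spectrum, 2, 0, 2)

    def test_idempotent_on_own_output(self, acgtt_spectrum):
        params = self._params()
        first = correct_read(ReadRecord("r", "ACGTT", "IIIII"), acgtt_spectrum, 2, params)
        again = correct_read(
            ReadRecord("r", first.corrected_sequence, first.corrected_qualities),
            acgtt_spectrum,
            2,
            params,
        )
        assert again.status == "unchanged"
        assert again.applied_edits == []


class TestCorrectDataset:
    def test_error_free_dataset_untouched(self, backbone_reads):
        _, reads = backbone_reads
        result = correct_dataset(reads, CorrectionParams(k=15, canonical=False))
        assert result.summary["corrected"] == 0
        assert result.summary["uncorrectable"] == 0
        assert result.summary["total_edits"] == 0
        assert all(len(rec.edits) == 0 for rec in result.applied_tef)
        assert len(result.applied_tef) == len(reads)

    def test_deterministic_applied_tef(self):
        from kspec.simulate import SimulationConfig, simulate_genome, simulate_reads

        genome = simulate_genome(2_000, 0.5, seed=6)
        config = SimulationConfig(read_length=80, coverage=25, substitution_rate=0.005, seed=6)
        dataset = simulate_reads(genome, config)
        params = CorrectionParams(k=13)
        lines = [
            "\n".join(tef_line(rec) for rec in correct_dataset(dataset.reads, params).applied_tef)
            for _ in range(2)
        ]
        assert lines[0] == lines[1]

    def test_edit_budget_respected(self):
        from kspec.simulate import SimulationConfig, simulate_genome, simulate_reads

        genome = simulate_genome(2_000, 0.5, seed=9)
        config = SimulationConfig(read_length=80, coverage=25, substitution_rate=0.02, seed=9)
        dataset = simulate_reads(genome, config)
        result = correct_dataset(dataset.reads, CorrectionParams(k=13))
        for outcome, read in zip(result.outcomes, dataset.reads):
            # global cap: short regions allow 2 edits, long ones 2x length;
            # a read can never accumulate more edits than twice its k-mer count
            assert len(outcome.applied_edits) <= 2 * (len(read.sequence) - 13 + 1)
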