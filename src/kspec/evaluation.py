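"""Evaluation of correction output against ground truth.

Corrections are scored per base: an error the corrector restored to its
true base is a true positive (TP); an error left alone or replaced with the
wrong base is a false negative (FN); a correct base the corrector altered
is a false positive (FP); every other base is a true negative (TN).  A
wrongly-replaced error base counts FN only — no appropriate base was
modified, so it is not also an FP.

From the confusion counts:

    gain      = (TP - FP) / (TP + FN)     net fraction of errors removed;
                                          negative when the corrector does
                                          more harm than good, 1.0 when it
                                          fixes everything and breaks nothing
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-score   = harmonic mean of precision and recall

Undefined ratios (zero denominators) are reported as NaN with an explicit
flag, never silently as 0.

The context profiler tabulates reference base tuples centred on error
positions (against a background of all tuples over each read's reference
span, extended by 6 bases each side to avoid coverage bias), exposing
sequence-composition preferences around miscalls.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .io_formats import TefEdit, TefRecord
from .spectrum import reverse_complement

__all__ = [
    "Confusion",
    "EvalResult",
    "ContextProfile",
    "classify_corrections",
    "classify_by_alignment",
    "metrics",
    "evaluate",
    "error_context_profile",
]


@dataclass
class Confusion:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "Confusion") -> "Confusion":
        return Confusion(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.TN + other.TN,
        )


@dataclass
class EvalResult:
    confusion: Confusion
    gain: float
    precision: float
    recall: float
    f_score: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            "TP": self.confusion.TP,
            "FP": self.confusion.FP,
            "FN": self.confusion.FN,
            "TN": self.confusion.TN,
            "gain": self.gain,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "undefined": sorted(self.undefined),
        }


def _by_read(records: Sequence[TefRecord], n_reads: int) -> list[dict[int, TefEdit]]:
    out: list[dict[int, TefEdit]] = [{} for _ in range(n_reads)]
    for rec in records:
        if rec.read_index >= n_reads:
            raise ValueError(f"read index {rec.read_index} out of range (n={n_reads})")
        for edit in rec.edits:
            out[rec.read_index][edit.position] = edit
    return out


def classify_corrections(
    truth: Sequence[TefRecord],
    applied: Sequence[TefRecord],
    read_lengths: Sequence[int],
) -> Confusion:
    """Positional TEF matching, substitution-only mode.

    ``truth`` and ``applied`` must index the same read ordering; every base
    of every read lands in exactly one confusion cell, so
    ``TP + FP + FN + TN == sum(read_lengths)``.
    """
    n = len(read_lengths)
    truth_by_read = _by_read(truth, n)
    applied_by_read = _by_read(applied, n)
    for name, per_read in (("truth", truth_by_read), ("applied", applied_by_read)):
        for idx, edits in enumerate(per_read):
            for pos, edit in edits.items():
                if edit.edit_type != "substitution":
                    raise ValueError(
                        f"{name} read {idx}: non-substitution edit at {pos}; "
                        "use classify_by_alignment for indel-mode evaluation"
                    )
                if pos >= read_lengths[idx]:
                    raise ValueError(
                        f"{name} read {idx}: position {pos} beyond read length "
                        f"{read_lengths[idx]}"
                    )
    conf = Confusion()
    for idx in range(n):
        t_edits = truth_by_read[idx]
        a_edits = applied_by_read[idx]
        for pos, t_edit in t_edits.items():
            a_edit = a_edits.get(pos)
            if a_edit is not None and a_edit.true == t_edit.true:
                conf.TP += 1
            else:
                conf.FN += 1  # untouched, or wrongly replaced (FN only)
        for pos in a_edits:
            if pos not in t_edits:
                conf.FP += 1
        conf.TN += read_lengths[idx] - len(t_edits.keys() | a_edits.keys())
    return conf


def apply_tef_edits(sequence: str, edits: Sequence[TefEdit]) -> str:
    """Reconstruct the true sequence by undoing the recorded errors.

    Substitution: the read base at ``position`` becomes ``true``; insertion
    (spurious read base): that base is removed; deletion (missing base):
    ``true`` is re-inserted before ``position``.  Positions refer to the
    read as sequenced, so edits are applied right-to-left.
    """
    out = sequence
    for edit in sorted(edits, key=lambda e: e.position, reverse=True):
        p = edit.position
        if edit.edit_type == "substitution":
            out = out[:p] + edit.true + out[p + 1 :]
        elif edit.edit_type == "insertion":
            out = out[:p] + out[p + 1 :]
        else:
            out = out[:p] + edit.true + out[p:]
    return out


def classify_by_alignment(
    original: str, corrected: str, true_read: str
) -> Confusion:
    """Alignment-based scoring for length-changing corrections.

    Aligns both the original and the corrected read to the ground-truth read
    (unit costs, leftmost-optimal path) and attributes errors to true-read
    coordinates.  TP = original error positions no longer erroneous after
    correction; FN = still erroneous; FP = newly erroneous positions; TN =
    remaining true-read positions.
    """

    def error_positions(query: str) -> set[int]:
        if not query:
            return set(range(len(true_read)))
        result = edlib.align(query, true_read, task="path", mode="NW")
        positions: set[int] = set()
        t = 0
        for length, op in _cigar_ops(result["cigar"]):
            if op == "=":
                t += length
            elif op in ("X", "D"):  # mismatch, or true base missing from query
                positions.update(range(t, t + length))
                t += length
            else:  # "I": spurious query base; attribute to the left junction
                positions.add(min(t, len(true_read) - 1))
        return positions

    before = error_positions(original)
    after = error_positions(corrected)
    tp = len(before - after)
    fn = len(before & after)
    fp = len(after - before)
    tn = len(true_read) - tp - fn - fp
    return Confusion(tp, fp, fn, tn)


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def metrics(confusion: Confusion) -> EvalResult:
    """Gain, precision, recall and F-score with explicit undefined flags."""
    tp, fp, fn = confusion.TP, confusion.FP, confusion.FN
    undefined = set()
    if tp + fn > 0:
        gain = (tp - fp) / (tp + fn)
        recall = tp / (tp + fn)
    else:
        gain = recall = math.nan
        undefined.update({"gain", "recall"})
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = math.nan
        undefined.add("precision")
    if undefined & {"precision", "recall"} or precision + recall == 0:
        f_score = math.nan
        undefined.add("f_score")
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return EvalResult(confusion, gain, precision, recall, f_score, frozenset(undefined))


def evaluate(
    truth: Sequence[TefRecord],
    applied: Sequence[TefRecord],
    read_lengths: Sequence[int],
) -> EvalResult:
    """Convenience: positional classification followed by metric computation."""
    return metrics(classify_corrections(truth, applied, read_lengths))


@dataclass
class ContextProfile:
    """Reference-tuple counts around error positions, plus background.

    Tuples are strings of width ``2*flank + 1`` in read orientation with the
    error slot at the centre.  ``skipped`` counts errors too close to a
    contig end to have a full tuple.
    """

    tuple_width: int
    counts: Counter = field(default_factory=Counter)
    background: Counter = field(default_factory=Counter)
    skipped: int = 0

    def preceding_base_frequencies(self) -> dict[str, float]:
        """Relative frequency of the base immediately before the error."""
        flank = self.tuple_width // 2
        totals: Counter = Counter()
        for tup, n in self.counts.items():
            totals[tup[flank - 1]] += n
        total = sum(totals.values())
        return {b: totals.get(b, 0) / total for b in "ACGT"} if total else {}


def error_context_profile(
    reference: str,
    read_placements: Sequence[tuple[int, str]],
    truth: Sequence[TefRecord],
    flank: int,
    read_lengths: Sequence[int] | None = None,
    background_pad: int = 6,
) -> ContextProfile:
    """Profile the reference sequence context around ground-truth errors.

    ``read_placements[i]`` is ``(ref_start, strand)`` for read ``i`` with
    strand "+" or "-"; the reference is used rather than the reads so
    neighbouring bases are never themselves miscalls.  Reverse-strand tuples
    are reverse-complemented into read orientation.  The background counts
    every tuple over each read's reference span padded by ``background_pad``
    bases on both sides, mirroring the read sampling rather than the whole
    reference (avoids GC coverage bias).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    width = 2 * flank + 1
    profile = ContextProfile(width)
    ref_len = len(reference)
    if read_lengths is None:
        read_lengths = [0] * len(read_placements)

    for rec in truth:
        ref_start, strand = read_placements[rec.read_index]
        read_len = read_lengths[rec.read_index]
        for edit in rec.edits:
            if edit.edit_type != "substitution":
                continue
            if strand == "+":
                ref_pos = ref_start + edit.position
            else:
                ref_pos = ref_start + read_len - 1 - edit.position
            lo, hi = ref_pos - flank, ref_pos + flank + 1
            if lo < 0 or hi > ref_len:
                profile.skipped += 1
                continue
            tup = reference[lo:hi]
            if strand == "-":
                tup = reverse_complement(tup)
            profile.counts[tup] += 1

    for idx, (ref_start, strand) in enumerate(read_placements):
        span_lo = max(0, ref_start - background_pad)
        span_hi = min(ref_len, ref_start + read_lengths[idx] + background_pad)
        segment = reference[span_lo:span_hi]
        if strand == "-":
            segment = reverse_complement(segment)
        for i in range(len(segment) - width + 1):
            profile.background[segment[i : i + width]] += 1
    return profile
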