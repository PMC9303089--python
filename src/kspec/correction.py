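"""Spectrum-based read correction.

A weak k-mer (k-count at or below the error threshold) is presumed to carry
a sequencing error.  Correction converts weak k-mers into solid ones by
minimal edits confined to the error regions where weakness is evidenced,
iterating per read until no weak k-mer remains or the read is declared
uncorrectable.  The spectrum and threshold are frozen for the whole run, so
results are deterministic and independent of read order.

Short regions (at most k k-mer starts — the footprint of a single error)
are fixed by exhaustive single-edit search; long regions by a greedy
left-to-right sweep that repairs the first weak k-mer at its rightmost base
(the first base that can explain a solid-to-weak transition) and re-scans.

Edit records use TEF semantics throughout: an edit's ``edit_type`` names the
*sequencing error being claimed*, so a base the corrector removes is
recorded as an insertion error (``I``: the read held a spurious base) and a
base the corrector adds as a deletion error (``D``: the read missed a base).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .error_regions import ErrorRegion, find_error_regions
from .io_formats import ReadRecord, TefEdit, TefRecord
from .spectrum import (
    CountingBloomParams,
    KmerSpectrum,
    build_spectrum,
    extract_kmers,
)
from .thresholding import (
    CountHistogram,
    ThresholdResult,
    count_histogram,
    threshold_first_minimum,
    threshold_zero_run,
)

__all__ = [
    "CorrectionParams",
    "EditCandidate",
    "CorrectionOutcome",
    "DatasetResult",
    "enumerate_candidates",
    "correct_short_region",
    "correct_long_region",
    "correct_read",
    "correct_dataset",
]

INSERTED_BASE_QUALITY = "#"
_BASES = "ACGT"


@dataclass(frozen=True)
class CorrectionParams:
    """Knobs for a correction run.

    ``threshold_method`` picks the t_er rule ("first_minimum" for shotgun
    data, "zero_run" for amplicons); ``canonical`` merges reverse-complement
    k-mers (on for shotgun, off for strand-specific amplicons).
    ``short_region_budget`` caps edits per short region; long regions are
    capped at twice their length.
    """

    k: int = 15
    threshold_method: str = "first_minimum"
    min_zero_run: int = 3
    canonical: bool = True
    backend: str = "exact"
    bloom_params: CountingBloomParams | None = None
    allow_indels: bool = False
    discard_policy: str = "keep"  # "keep" | "drop"
    trim_ends: bool = False
    short_region_budget: int = 2
    max_rounds: int = 30
    bandwidth: float | None = None
    extend_regions: bool = True


@dataclass(frozen=True)
class EditCandidate:
    """A single-base edit with its post-edit support.

    ``min_count``/``total_count`` summarise the k-counts of the k-mers that
    overlap the edited base after the edit; candidates are ranked by
    ``sort_key`` (highest minimum support first, substitutions preferred
    over indels, then highest total, leftmost position, alphabetical base).
    """

    position: int
    edit_type: str  # "substitution" | "insertion" | "deletion" (read operation)
    replacement: str  # new base, or "" for a deletion
    min_count: int
    total_count: int

    @property
    def sort_key(self) -> tuple:
        return (
            -self.min_count,
            0 if self.edit_type == "substitution" else 1,
            -self.total_count,
            self.position,
            self.replacement,
        )


@dataclass
class CorrectionOutcome:
    """Result of correcting one read."""

    read_index: int
    status: str  # "corrected" | "unchanged" | "uncorrectable" | "discarded"
    corrected_sequence: str
    corrected_qualities: str | None
    applied_edits: list[TefEdit] = field(default_factory=list)
    iterations_used: int = 0
    trimmed: tuple[int, int] = (0, 0)  # bases removed from (start, end)


def _apply_op(sequence: str, op: str, position: int, replacement: str) -> str:
    if op == "substitution":
        return sequence[:position] + replacement + sequence[position + 1 :]
    if op == "deletion":
        return sequence[:position] + sequence[position + 1 :]
    if op == "insertion":
        return sequence[:position] + replacement + sequence[position:]
    raise ValueError(f"unknown edit operation {op!r}")


def _window_support(
    sequence: str,
    spectrum: KmerSpectrum,
    lo_start: int,
    hi_start: int,
) -> tuple[int, int] | None:
    """(min, total) k-count over valid k-mers starting in [lo_start, hi_start].

    Returns None when no window in the range is N-free (no evidence).
    """
    k = spectrum.k
    lo = max(0, lo_start)
    hi = min(hi_start, len(sequence) - k)
    counts = []
    for p in range(lo, hi + 1):
        kmer = sequence[p : p + k]
        if "N" in kmer:
            continue
        counts.append(spectrum.kcount(kmer))
    if not counts:
        return None
    return min(counts), sum(counts)


def _single_edit_ops(
    sequence: str, position: int, allow_indels: bool
) -> list[tuple[str, str]]:
    """All single-edit operations at a base position: (op, replacement)."""
    ops: list[tuple[str, str]] = []
    current = sequence[position]
    for base in _BASES:
        if base != current:
            ops.append(("substitution", base))
    if allow_indels:
        ops.append(("deletion", ""))
        for base in _BASES:
            ops.append(("insertion", base))
    return ops


def _candidates_at(
    sequence: str,
    position: int,
    spectrum: KmerSpectrum,
    t_er: int,
    allow_indels: bool,
    eval_hi_start: int | None = None,
) -> list[EditCandidate]:
    """Surviving single-edit candidates at one base position.

    A candidate survives when every N-free k-mer overlapping the edited base
    (start positions ``[position - k + 1, position]``, optionally capped at
    ``eval_hi_start``) is solid after the edit.
    """
    k = spectrum.k
    out = []
    for op, repl in _single_edit_ops(sequence, position, allow_indels):
        edited = _apply_op(sequence, op, position, repl)
        if len(edited) < k:
            continue
        hi = position  # for deletions `position` is the junction left behind
        if eval_hi_start is not None:
            hi = min(hi, eval_hi_start)
        support = _window_support(edited, spectrum, position - k + 1, hi)
        if support is None:
            continue
        mn, total = support
        if mn <= t_er:
            continue
        out.append(EditCandidate(position, op, repl, mn, total))
    return out


def enumerate_candidates(
    read: ReadRecord | str,
    region: ErrorRegion,
    spectrum: KmerSpectrum,
    t_er: int,
    allow_indels: bool = False,
) -> list[EditCandidate]:
    """All surviving single edits within a region's base window, ranked."""
    sequence = read if isinstance(read, str) else read.sequence
    k = spectrum.k
    lo, hi = region.base_window(k)
    hi = min(hi, len(sequence) - 1)
    candidates: list[EditCandidate] = []
    for position in range(lo, hi + 1):
        candidates.extend(
            _candidates_at(sequence, position, spectrum, t_er, allow_indels)
        )
    return sorted(candidates, key=lambda c: c.sort_key)


def _weak_starts(
    sequence: str, spectrum: KmerSpectrum, t_er: int, lo: int, hi: int
) -> list[int]:
    """Weak k-mer start positions within [lo, hi], clipped to the read."""
    k = spectrum.k
    lo = max(0, lo)
    hi = min(hi, len(sequence) - k)
    weak = []
    for p in range(lo, hi + 1):
        kmer = sequence[p : p + k]
        if "N" in kmer:
            continue
        if spectrum.kcount(kmer) <= t_er:
            weak.append(p)
    return weak


def correct_short_region(
    sequence: str,
    region: ErrorRegion,
    spectrum: KmerSpectrum,
    t_er: int,
    allow_indels: bool = False,
    budget: int = 2,
) -> tuple[str, list[EditCandidate]] | None:
    """Fix a short region by exhaustive single-edit search.

    Applies the best-ranked candidate; if weak k-mers remain in the window,
    recurses with the remaining budget.  Returns ``None`` (uncorrectable)
    when no candidate survives or the budget is exhausted.  A region that is
    already solid on re-check returns unchanged (stale-region idempotence).
    """
    applied: list[EditCandidate] = []
    current = sequence
    reg = region
    for _ in range(budget):
        if not _weak_starts(current, spectrum, t_er, reg.start, reg.end):
            return current, applied
        candidates = enumerate_candidates(current, reg, spectrum, t_er, allow_indels)
        if not candidates:
            return None
        best = candidates[0]
        current = _apply_op(current, best.edit_type, best.position, best.replacement)
        applied.append(best)
        delta = {"substitution": 0, "insertion": 1, "deletion": -1}[best.edit_type]
        reg = replace(reg, end=reg.end + delta) if delta else reg
    if _weak_starts(current, spectrum, t_er, reg.start, reg.end):
        return None
    return current, applied


def correct_long_region(
    sequence: str,
    region: ErrorRegion,
    spectrum: KmerSpectrum,
    t_er: int,
    allow_indels: bool = False,
) -> tuple[str, list[EditCandidate]] | None:
    """Fix a long region greedily from the left.

    Repeatedly locates the leftmost weak k-mer start ``p`` and tries a
    single edit at base ``p + k - 1`` — the rightmost base of the first weak
    k-mer, the earliest base that can explain the solid-to-weak transition —
    sliding the attempted base leftward within that k-mer on failure.  An
    edit is accepted only if every k-mer overlapping it up to start ``p``
    becomes solid.  Edits are capped at twice the region length.
    """
    k = spectrum.k
    current = sequence
    end = region.end
    applied: list[EditCandidate] = []
    max_edits = 2 * region.length
    while True:
        weak = _weak_starts(current, spectrum, t_er, region.start, end)
        if not weak:
            return current, applied
        if len(applied) >= max_edits:
            return None
        p = weak[0]
        success = None
        for b in range(min(p + k - 1, len(current) - 1), p - 1, -1):
            candidates = _candidates_at(
                current, b, spectrum, t_er, allow_indels, eval_hi_start=p
            )
            if candidates:
                success = min(candidates, key=lambda c: c.sort_key)
                break
        if success is None:
            return None
        current = _apply_op(
            current, success.edit_type, success.position, success.replacement
        )
        applied.append(success)
        end += {"substitution": 0, "insertion": 1, "deletion": -1}[success.edit_type]


def _trim_weak_ends(
    sequence: str, spectrum: KmerSpectrum, t_er: int
) -> tuple[int, int]:
    """(left, right) trim lengths: bases participating only in weak k-mers.

    Each side trims at most k - 1 bases, so no read is consumed entirely by
    trimming.
    """
    k = spectrum.k
    n = len(sequence)
    if n < k:
        return 0, 0

    def weak_at(p: int) -> bool:
        kmer = sequence[p : p + k]
        return "N" not in kmer and spectrum.kcount(kmer) <= t_er

    left = 0
    while left < k - 1:
        # base `left` participates in k-mer starts [0-ish..left]
        starts = range(max(0, left - k + 1), min(left, n - k) + 1)
        if starts and all(weak_at(p) for p in starts):
            left += 1
        else:
            break
    right = 0
    while right < k - 1:
        b = n - 1 - right
        starts = range(max(0, b - k + 1), min(b, n - k) + 1)
        if starts and all(weak_at(p) for p in starts):
            right += 1
        else:
            break
    if left + right >= n:
        return 0, 0
    return left, right


class _QualityTracker:
    """Keeps qualities and original-coordinate mapping in sync with edits."""

    def __init__(self, read: ReadRecord):
        self.quals = list(read.qualities) if read.qualities is not None else None
        self.origin = list(range(len(read.sequence)))

    def original_position(self, current_pos: int) -> int:
        if current_pos < len(self.origin):
            o = self.origin[current_pos]
            if o >= 0:
                return o
            # corrector-inserted base: anchor to the next original base
            for nxt in self.origin[current_pos + 1 :]:
                if nxt >= 0:
                    return nxt
        for prev in reversed(self.origin[:current_pos]):
            if prev >= 0:
                return prev + 1
        return 0

    def apply(self, cand: EditCandidate) -> None:
        p = cand.position
        if cand.edit_type == "substitution":
            return
        if cand.edit_type == "deletion":
            del self.origin[p]
            if self.quals is not None:
                del self.quals[p]
        else:
            self.origin.insert(p, -1)
            if self.quals is not None:
                self.quals.insert(p, INSERTED_BASE_QUALITY)

    def quality_string(self) -> str | None:
        return "".join(self.quals) if self.quals is not None else None


# TEF edit_type names the *sequencing error*, so read operations flip:
# removing a read base claims the sequencer inserted it, and vice versa.
_OP_TO_ERROR = {"substitution": "substitution", "deletion": "insertion", "insertion": "deletion"}


def correct_read(
    read: ReadRecord,
    spectrum: KmerSpectrum,
    threshold: ThresholdResult | int,
    params: CorrectionParams,
    read_index: int = 0,
) -> CorrectionOutcome:
    """Correct one read against a frozen spectrum and threshold.

    Error regions are recomputed after every successful region fix; the
    loop ends when no weak k-mer remains (``corrected`` / ``unchanged``) or
    no remaining region can be fixed (``uncorrectable``, or ``discarded``
    under the drop policy).  Corrections never feed back into the spectrum.
    """
    t_er = threshold.t_er if isinstance(threshold, ThresholdResult) else threshold
    k = params.k
    sequence = read.sequence
    tracker = _QualityTracker(read)
    applied: list[TefEdit] = []
    status = "uncorrectable"  # overwritten unless max_rounds is exhausted
    iterations = 0
    for iterations in range(1, params.max_rounds + 1):
        current = ReadRecord(read.read_id, sequence, None)
        regions = find_error_regions(
            current,
            spectrum,
            t_er,
            k,
            read_index=read_index,
            bandwidth=params.bandwidth,
            extend=params.extend_regions,
        )
        if not regions:
            status = "corrected" if applied else "unchanged"
            break
        progressed = False
        for region in regions:
            if region.kind == "short":
                result = correct_short_region(
                    sequence,
                    region,
                    spectrum,
                    t_er,
                    params.allow_indels,
                    params.short_region_budget,
                )
            else:
                result = correct_long_region(
                    sequence, region, spectrum, t_er, params.allow_indels
                )
            if result is None:
                continue  # this region is uncorrectable; try the next
            new_sequence, cands = result
            for cand in cands:
                obs = sequence[cand.position] if cand.edit_type != "insertion" else "-"
                true = cand.replacement if cand.replacement else "-"
                applied.append(
                    TefEdit(
                        tracker.original_position(cand.position),
                        obs,
                        true,
                        _OP_TO_ERROR[cand.edit_type],
                    )
                )
                tracker.apply(cand)
                sequence = _apply_op(
                    sequence, cand.edit_type, cand.position, cand.replacement
                )
            assert sequence == new_sequence
            if cands:
                progressed = True
                break  # region list is stale after edits; recompute
        if not progressed:
            status = "uncorrectable"
            break

    trimmed = (0, 0)
    if params.trim_ends and status == "uncorrectable":
        left, right = _trim_weak_ends(sequence, spectrum, t_er)
        if left or right:
            sequence = sequence[left : len(sequence) - right]
            if tracker.quals is not None:
                tracker.quals = tracker.quals[left : len(tracker.quals) - right]
            tracker.origin = tracker.origin[left : len(tracker.origin) - right]
            trimmed = (left, right)
            if not _weak_starts(sequence, spectrum, t_er, 0, len(sequence) - k):
                status = "corrected"

    if status == "uncorrectable" and params.discard_policy == "drop":
        status = "discarded"
    applied.sort()
    return CorrectionOutcome(
        read_index,
        status,
        sequence,
        tracker.quality_string(),
        applied,
        iterations,
        trimmed,
    )


@dataclass
class DatasetResult:
    """Everything a correction run produces."""

    outcomes: list[CorrectionOutcome]
    applied_tef: list[TefRecord]
    spectrum: KmerSpectrum
    histogram: CountHistogram | None
    threshold: ThresholdResult
    summary: dict

    def corrected_reads(self, reads: list[ReadRecord]) -> list[ReadRecord]:
        """Output reads (original ids, corrected sequences), drops excluded."""
        out = []
        for read, outcome in zip(reads, self.outcomes):
            if outcome.status == "discarded":
                continue
            out.append(
                ReadRecord(read.read_id, outcome.corrected_sequence, outcome.corrected_qualities)
            )
        return out


def _histogram_from_read_pass(
    reads: list[ReadRecord], spectrum: KmerSpectrum
) -> CountHistogram:
    """Estimate f(v) from a Bloom-backed spectrum by one pass over reads.

    A Bloom filter cannot enumerate its keys, so each k-mer *instance* is
    queried and the instance mass at count v is divided by v (a k-mer with
    count v contributes v instances).  Repeated instances of the same k-mer
    are all counted, which is exactly what the division corrects for.
    """
    instance_mass: dict[int, int] = {}
    for read in reads:
        for kmer, _ in extract_kmers(read.sequence, spectrum.k):
            v = spectrum.kcount(kmer)
            instance_mass[v] = instance_mass.get(v, 0) + 1
    freqs = {v: max(1, round(mass / v)) for v, mass in instance_mass.items() if v > 0}
    return CountHistogram(freqs)


def derive_threshold(
    hist: CountHistogram, method: str, min_zero_run: int = 3
) -> ThresholdResult:
    if method == "first_minimum":
        return threshold_first_minimum(hist)
    if method == "zero_run":
        return threshold_zero_run(hist, min_zero_run)
    raise ValueError(f"unknown threshold method {method!r}")


def correct_dataset(
    reads: list[ReadRecord], params: CorrectionParams
) -> DatasetResult:
    """Correct a whole read set: one spectrum, one threshold, per-read fixes.

    ``applied_tef`` holds one record per input read (empty-edit lines for
    untouched reads) with positions in original-read coordinates, ready to
    compare against simulator ground truth.
    """
    spectrum = build_spectrum(
        reads,
        params.k,
        backend=params.backend,
        canonical=params.canonical,
        bloom_params=params.bloom_params,
    )
    if spectrum.backend == "exact":
        hist = count_histogram(spectrum)
    else:
        hist = _histogram_from_read_pass(reads, spectrum)
    threshold = derive_threshold(hist, params.threshold_method, params.min_zero_run)
    outcomes = []
    applied_tef = []
    summary = {"corrected": 0, "unchanged": 0, "uncorrectable": 0, "discarded": 0}
    total_edits = 0
    for idx, read in enumerate(reads):
        if len(read.sequence) < params.k:
            outcome = CorrectionOutcome(
                idx, "unchanged", read.sequence, read.qualities, [], 0
            )
        else:
            outcome = correct_read(read, spectrum, threshold, params, read_index=idx)
        outcomes.append(outcome)
        applied_tef.append(TefRecord(idx, tuple(outcome.applied_edits)))
        summary[outcome.status] += 1
        total_edits += len(outcome.applied_edits)
    summary["total_edits"] = total_edits
    summary["t_er"] = threshold.t_er
    return DatasetResult(outcomes, applied_tef, spectrum, hist, threshold, summary)
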