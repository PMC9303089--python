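"""Per-read error-region discovery.

An error region of a read is a maximal interval ``[i, j]`` of k-mer start
positions whose k-mers are all weak (k-count <= t_er), optionally *extended*
into neighbouring positions whose k-counts fall in the same mean-shift
cluster as positions already in the region, with overlapping or adjacent
extended regions merged.  Regions of length <= k (in k-mer starts) are
*short* — consistent with a single error — and longer ones are *long*.

Clustering groups the read's k-count profile into coverage strata; the
extension rule pulls in flanking positions whose counts look like the weak
core rather than like the solid background, capturing error k-mers whose
counts are slightly inflated by chance collisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ReadRecord
from .spectrum import KmerSpectrum, extract_kmers

__all__ = [
    "ErrorRegion",
    "ClusterLabels",
    "find_weak_segments",
    "mean_shift_1d",
    "cluster_kcounts",
    "extend_and_merge",
    "find_error_regions",
]

MEAN_SHIFT_TOL = 1e-6
MEAN_SHIFT_MAX_ITER = 500


@dataclass(frozen=True)
class ErrorRegion:
    """Interval of k-mer start positions flagged as erroneous, inclusive ends."""

    read_index: int
    start: int
    end: int
    kind: str  # "short" | "long"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def base_window(self, k: int) -> tuple[int, int]:
        """Base-coordinate span ``[start, end + k - 1]`` covered by the region."""
        return self.start, self.end + k - 1


@dataclass
class ClusterLabels:
    """Mean-shift cluster assignment of a read's k-mer positions.

    ``labels[p]`` is the cluster id of the k-mer starting at ``p``, or -1
    where the k-mer contains N (no valid k-count).  ``modes`` maps cluster
    id to the converged mode k-count.
    """

    labels: np.ndarray
    modes: dict[int, float]


def _kcount_profile(read: ReadRecord, spectrum: KmerSpectrum, k: int) -> np.ndarray:
    """k-counts per start position; -1 marks N-containing (invalid) windows."""
    n_pos = len(read.sequence) - k + 1
    profile = np.full(max(n_pos, 0), -1, dtype=np.int64)
    for kmer, pos in extract_kmers(read.sequence, k):
        profile[pos] = spectrum.kcount(kmer)
    return profile


def find_weak_segments(
    read: ReadRecord, spectrum: KmerSpectrum, t_er: int, k: int
) -> list[tuple[int, int]]:
    """Maximal runs of start positions whose k-mers are weak (kc <= t_er).

    Positions with N-containing k-mers carry no count evidence; they break
    runs.  A read shorter than k has no k-mers and yields an empty list.
    """
    profile = _kcount_profile(read, spectrum, k)
    segments: list[tuple[int, int]] = []
    start = None
    for p, count in enumerate(profile):
        weak = 0 <= count <= t_er
        if weak and start is None:
            start = p
        elif not weak and start is not None:
            segments.append((start, p - 1))
            start = None
    if start is not None:
        segments.append((start, len(profile) - 1))
    return segments


def mean_shift_1d(
    values: np.ndarray,
    bandwidth: float,
    tol: float = MEAN_SHIFT_TOL,
    max_iter: int = MEAN_SHIFT_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-kernel mean shift on a 1-D sample.

    Each point iterates ``x <- mean{y : |y - x| <= h}`` to a fixed point;
    points whose converged modes differ by at most ``h/2`` share a label.
    Returns ``(labels, modes_per_point)``.
    """
    values = np.asarray(values, dtype=float)
    x = values.copy()
    for _ in range(max_iter):
        # pairwise window membership: points of the *sample* within h of each x
        within = np.abs(values[None, :] - x[:, None]) <= bandwidth
        new_x = (within * values[None, :]).sum(axis=1) / within.sum(axis=1)
        if np.abs(new_x - x).max() <= tol:
            x = new_x
            break
        x = new_x
    order = np.argsort(x, kind="stable")
    labels = np.empty(len(x), dtype=np.int64)
    current = -1
    prev_mode = None
    for idx in order:
        if prev_mode is None or x[idx] - prev_mode > bandwidth / 2:
            current += 1
        labels[idx] = current
        prev_mode = x[idx]
    return labels, x


def default_bandwidth(counts: np.ndarray) -> float:
    """``max(2, MAD)`` of the k-count sample — a robust spread estimate."""
    med = np.median(counts)
    mad = np.median(np.abs(counts - med))
    return float(max(2.0, mad))


def cluster_kcounts(
    read: ReadRecord,
    spectrum: KmerSpectrum,
    k: int,
    bandwidth: float | None = None,
) -> ClusterLabels:
    """Cluster all valid k-mer positions of a read by their k-counts."""
    profile = _kcount_profile(read, spectrum, k)
    labels = np.full(len(profile), -1, dtype=np.int64)
    valid = profile >= 0
    counts = profile[valid]
    if counts.size == 0:
        return ClusterLabels(labels, {})
    if bandwidth is None:
        bandwidth = default_bandwidth(counts)
    point_labels, point_modes = mean_shift_1d(counts.astype(float), bandwidth)
    labels[valid] = point_labels
    modes: dict[int, float] = {}
    for lab, mode in zip(point_labels, point_modes):
        modes.setdefault(int(lab), float(mode))
    return ClusterLabels(labels, modes)


def extend_and_merge(
    segments: list[tuple[int, int]],
    labels: ClusterLabels,
    k: int,
    read_length: int,
    read_index: int = 0,
) -> list[ErrorRegion]:
    """Grow weak segments along shared clusters, merge, and classify.

    Each segment grows outward one position at a time while the adjacent
    position's cluster label matches the label of some position already in
    the (growing) segment, iterated to a fixed point; positions with no
    valid label stop growth.  Overlapping or adjacent grown segments merge.
    """
    n_pos = read_length - k + 1
    lab = labels.labels
    grown: list[tuple[int, int]] = []
    for start, end in segments:
        seg_labels = {int(l) for l in lab[start : end + 1] if l >= 0}
        changed = True
        while changed:
            changed = False
            if start > 0 and lab[start - 1] >= 0 and int(lab[start - 1]) in seg_labels:
                start -= 1
                seg_labels.add(int(lab[start]))
                changed = True
            if end < n_pos - 1 and lab[end + 1] >= 0 and int(lab[end + 1]) in seg_labels:
                end += 1
                seg_labels.add(int(lab[end]))
                changed = True
        grown.append((start, end))
    grown.sort()
    merged: list[list[int]] = []
    for start, end in grown:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [
        ErrorRegion(read_index, s, e, "short" if e - s + 1 <= k else "long")
        for s, e in merged
    ]


def find_error_regions(
    read: ReadRecord,
    spectrum: KmerSpectrum,
    t_er: int,
    k: int,
    read_index: int = 0,
    bandwidth: float | None = None,
    extend: bool = True,
) -> list[ErrorRegion]:
    """Full per-read region discovery: weak runs, cluster extension, merge."""
    segments = find_weak_segments(read, spectrum, t_er, k)
    if not segments:
        return []
    if extend:
        labels = cluster_kcounts(read, spectrum, k, bandwidth)
        return extend_and_merge(segments, labels, k, len(read.sequence), read_index)
    merged = [
        ErrorRegion(read_index, s, e, "short" if e - s + 1 <= k else "long")
        for s, e in segments
    ]
    return merged
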