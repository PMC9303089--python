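"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations — exact-arithmetic or
enumeration based — kept separate from the implementation they check.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from typing import Sequence


def brute_force_kmer_counts(sequences: Sequence[str], k: int) -> Counter:
    """Naive dictionary of N-free k-mer counts built by direct iteration."""
    counts: Counter = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    return counts


def mean_shift_partition_oracle(
    values: Sequence[float], bandwidth: float
) -> list[frozenset[int]]:
    """Exact flat-kernel mode seeking with Fraction arithmetic.

    Iterates each point to its fixed point under x <- mean of sample points
    within the bandwidth window, then groups points whose modes differ by at
    most bandwidth/2.  Returns the partition of point indices.
    """
    h = Fraction(bandwidth).limit_denominator(10**6)
    vals = [Fraction(v).limit_denominator(10**6) for v in values]
    modes: list[Fraction] = []
    for x in vals:
        for _ in range(10_000):
            window = [y for y in vals if abs(y - x) <= h]
            nxt = sum(window) / len(window)
            if nxt == x:
                break
            x = nxt
        modes.append(x)
    order = sorted(range(len(vals)), key=lambda i: modes[i])
    groups: list[list[int]] = []
    prev = None
    for idx in order:
        if prev is None or modes[idx] - prev > h / 2:
            groups.append([])
        groups[-1].append(idx)
        prev = modes[idx]
    return [frozenset(g) for g in groups]


def labels_to_partition(labels: Sequence[int]) -> list[frozenset[int]]:
    """Canonical partition view of a label vector (ignores -1 entries)."""
    by_label: dict[int, set[int]] = {}
    for idx, lab in enumerate(labels):
        if lab >= 0:
            by_label.setdefault(int(lab), set()).add(idx)
    return sorted((frozenset(v) for v in by_label.values()), key=min)
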