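"""k-count histogram and error-threshold detection.

Sequencing errors produce rare k-mers, genuine genomic k-mers recur at
roughly coverage depth, so the distribution ``f(v)`` — how many distinct
k-mers have k-count ``v`` — is bimodal: an error mass near ``v = 1`` and a
coverage mode.  The error threshold ``t_er`` sits in the valley; a k-mer
``s`` is *weak* (presumed erroneous) iff ``kc(s) <= t_er``, *solid*
otherwise.

Two detection rules are provided:

``first_minimum``
    The first interior minimum of ``f(v)`` scanning upward from ``v = 1``
    on a zero-filled axis.  Suits shotgun data with a smooth valley.

``zero_run``
    The end of the first sufficiently long run of consecutive ``f(v) = 0``
    values.  Suits amplicon data, whose k-count distribution is strongly
    discontinuous; falls back to ``first_minimum`` when no qualifying run
    exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log
from pathlib import Path

import numpy as np

from .spectrum import KmerSpectrum

__all__ = [
    "CountHistogram",
    "ThresholdResult",
    "count_histogram",
    "threshold_first_minimum",
    "threshold_zero_run",
    "suggest_k",
]

DEFAULT_MIN_ZERO_RUN = 3


@dataclass
class CountHistogram:
    """``f(v)``: number of distinct k-mers with k-count ``v``."""

    freqs: dict[int, int] = field(default_factory=dict)

    @property
    def max_v(self) -> int:
        return max(self.freqs, default=0)

    @property
    def total_distinct(self) -> int:
        return sum(self.freqs.values())

    def f(self, v: int) -> int:
        """``f(v)`` on the zero-filled axis (absent values are 0)."""
        return self.freqs.get(v, 0)

    def dense(self) -> np.ndarray:
        """``f`` evaluated on every integer ``v`` in ``[1, max_v]``."""
        out = np.zeros(self.max_v, dtype=np.int64)
        for v, count in self.freqs.items():
            out[v - 1] = count
        return out

    def dump_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for v in range(1, self.max_v + 1):
                out.write(f"{v}\t{self.f(v)}\n")


@dataclass
class ThresholdResult:
    """Detected error threshold and how it was obtained.

    ``warning`` is set when the rule degenerated (no interior minimum found)
    and ``t_er = 0`` was returned, meaning only never-seen k-mers are weak.
    """

    t_er: int
    method: str
    warning: bool = False
    diagnostics: dict = field(default_factory=dict)

    def is_weak(self, kcount: int) -> bool:
        return kcount <= self.t_er


def count_histogram(spectrum: KmerSpectrum) -> CountHistogram:
    """Tabulate ``f(v)`` from an exact-backend spectrum.

    A Bloom-backed spectrum has no enumerable key set and its overcounts
    distort ``f(v)``; histogram construction therefore requires the exact
    backend.
    """
    if spectrum.backend != "exact":
        raise ValueError("count_histogram requires an exact-backend spectrum")
    freqs: dict[int, int] = {}
    for count in spectrum.counts.values():
        freqs[count] = freqs.get(count, 0) + 1
    return CountHistogram(freqs)


def threshold_first_minimum(hist: CountHistogram) -> ThresholdResult:
    """``t_er`` = first interior minimum of ``f(v)`` on the zero-filled axis.

    Concretely the smallest ``v >= 1`` with ``f(v) <= f(v+1)``; if ``f``
    decreases monotonically to ``max_v`` (no interior minimum), returns
    ``t_er = 0`` with ``warning=True``.
    """
    max_v = hist.max_v
    for v in range(1, max_v):
        if hist.f(v) <= hist.f(v + 1):
            return ThresholdResult(v, "first_minimum", diagnostics={"scanned_to": v + 1})
    return ThresholdResult(0, "first_minimum", warning=True, diagnostics={"scanned_to": max_v})


def threshold_zero_run(
    hist: CountHistogram, min_run_length: int = DEFAULT_MIN_ZERO_RUN
) -> ThresholdResult:
    """``t_er`` = end of the first run of >= ``min_run_length`` zeros in ``f``.

    Scans ``v = 1..max_v`` on the zero-filled axis for the first maximal run
    of consecutive ``v`` with ``f(v) = 0`` of sufficient length; ``t_er`` is
    the last ``v`` of that run.  With no qualifying run the rule is
    undefined and :func:`threshold_first_minimum` decides instead.
    """
    if min_run_length < 1:
        raise ValueError("min_run_length must be >= 1")
    run_start = None
    for v in range(1, hist.max_v + 1):
        if hist.f(v) == 0:
            if run_start is None:
                run_start = v
        else:
            if run_start is not None and v - run_start >= min_run_length:
                return ThresholdResult(
                    v - 1, "zero_run", diagnostics={"run": (run_start, v - 1)}
                )
            run_start = None
    # A trailing zero run cannot occur: f(max_v) > 0 by construction.
    fallback = threshold_first_minimum(hist)
    fallback.diagnostics["zero_run_fallback"] = True
    return fallback


def suggest_k(genome_length: int) -> int:
    """Rule-of-thumb k for a genome of the given length: ``ceil(log4 |G|)``.

    The smallest k whose 4^k k-mer space is at least the genome size, so
    random k-mer collisions are rare.
    """
    if genome_length < 4:
        raise ValueError("genome_length must be >= 4")
    k = ceil(log(genome_length, 4))
    # Guard against floating-point edge cases at exact powers of four.
    while 4**k < genome_length:
        k += 1
    while k > 1 and 4 ** (k - 1) >= genome_length:
        k -= 1
    return k
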