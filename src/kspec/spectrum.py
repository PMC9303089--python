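"""k-mer spectrum construction: exact hash-map counts and a counting Bloom filter.

A *k-spectrum* is the multiset of all length-``k`` substrings (k-mers) of a
read collection together with their occurrence counts (*k-counts*, ``kc(s)``).
Two interchangeable backends are provided:

``exact``
    A plain dictionary from k-mer string to count.  Ground truth for every
    downstream step.

``counting_bloom``
    A counting Bloom filter: an array of small saturating counters addressed
    by ``num_hashes`` seeded hash functions.  Counts reported for any query
    are *at least* the true count (hash collisions can only inflate them),
    so membership queries have no false negatives.

k-mers containing ``N`` are never counted and never queried by the rest of
the pipeline.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from math import ceil, log
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .io_formats import ReadRecord

__all__ = [
    "extract_kmers",
    "reverse_complement",
    "canonical_kmer",
    "CountingBloomParams",
    "CountingBloomFilter",
    "KmerSpectrum",
    "build_spectrum",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def extract_kmers(sequence: str, k: int) -> Iterator[tuple[str, int]]:
    """Yield ``(kmer, start_position)`` for every N-free k-mer of ``sequence``.

    A sequence shorter than ``k`` yields nothing.  Windows containing ``N``
    are skipped (standard practice: ambiguous bases carry no count evidence).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(sequence)
    if n < k:
        return
    # Track the most recent N so each window is checked in O(1).
    last_n = -1
    for i, base in enumerate(sequence[: k - 1]):
        if base == "N":
            last_n = i
    for start in range(n - k + 1):
        end = start + k - 1
        if sequence[end] == "N":
            last_n = end
        if last_n < start:
            yield sequence[start : start + k], start


@dataclass(frozen=True)
class CountingBloomParams:
    """Sizing and hashing parameters for the counting Bloom filter.

    ``bits_per_counter`` sets the saturation ceiling ``2**bits - 1``; counters
    saturate, never wrap, preserving the count-lower-bound guarantee.
    """

    num_counters: int = 1 << 20
    bits_per_counter: int = 8
    num_hashes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_counters < 1 or self.num_hashes < 1 or self.bits_per_counter < 1:
            raise ValueError("Bloom parameters must be positive")

    @classmethod
    def sized_for(
        cls,
        expected_distinct: int,
        false_positive_rate: float = 0.01,
        *,
        num_hashes: int = 4,
        bits_per_counter: int = 8,
        seed: int = 0,
    ) -> "CountingBloomParams":
        """Size the counter array for a target false-positive rate.

        Uses the standard Bloom relation ``m = -n ln p / (ln 2)^2``.
        """
        if not 0 < false_positive_rate < 1:
            raise ValueError("false_positive_rate must be in (0, 1)")
        n = max(1, expected_distinct)
        m = ceil(-n * log(false_positive_rate) / (log(2) ** 2))
        return cls(max(64, m), bits_per_counter, num_hashes, seed)


class CountingBloomFilter:
    """Counting Bloom filter with saturating counters and double hashing.

    The j-th hash is ``h1 + j*h2 (mod m)`` where ``h1``/``h2`` are the two
    halves of a keyed 128-bit blake2b digest; the key is derived from the
    seed, so identical input and seed give an identical filter.
    """

    def __init__(self, params: CountingBloomParams):
        self.params = params
        self._max = (1 << params.bits_per_counter) - 1
        dtype = np.uint8 if params.bits_per_counter <= 8 else np.uint64
        self.counters = np.zeros(params.num_counters, dtype=dtype)
        self._key = params.seed.to_bytes(8, "little", signed=True)

    def _indices(self, item: str) -> np.ndarray:
        digest = hashlib.blake2b(item.encode(), digest_size=16, key=self._key).digest()
        h1 = int.from_bytes(digest[:8], "little")
        h2 = int.from_bytes(digest[8:], "little") | 1
        m = self.params.num_counters
        return np.array(
            [(h1 + j * h2) % m for j in range(self.params.num_hashes)], dtype=np.int64
        )

    def add(self, item: str, count: int = 1) -> None:
        idx = self._indices(item)
        vals = self.counters[idx].astype(np.int64) + count
        self.counters[idx] = np.minimum(vals, self._max)

    def count(self, item: str) -> int:
        """Minimum over the item's counter cells; >= true insertion count."""
        return int(self.counters[self._indices(item)].min())

    def __contains__(self, item: str) -> bool:
        return self.count(item) > 0


@dataclass
class KmerSpectrum:
    """k-mer -> k-count map with a fixed ``k`` and a declared backend."""

    k: int
    backend: str  # "exact" | "counting_bloom"
    canonical: bool = False
    counts: Counter = field(default_factory=Counter)
    bloom: CountingBloomFilter | None = None
    total_instances: int = 0
    distinct: int = 0  # exact backend only

    def _key(self, kmer: str) -> str:
        return canonical_kmer(kmer) if self.canonical else kmer

    def kcount(self, kmer: str) -> int:
        """k-count of ``kmer`` (exact, or a >=-exact Bloom estimate)."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        key = self._key(kmer)
        if self.backend == "exact":
            return self.counts.get(key, 0)
        assert self.bloom is not None
        return self.bloom.count(key)

    def add(self, kmer: str, count: int = 1) -> None:
        key = self._key(kmer)
        if self.backend == "exact":
            if key not in self.counts:
                self.distinct += 1
            self.counts[key] += count
        else:
            assert self.bloom is not None
            self.bloom.add(key, count)
        self.total_instances += count

    def dump_tsv(self, path: str | Path) -> None:
        """Write (kmer, count) pairs, sorted, for debugging (exact backend)."""
        if self.backend != "exact":
            raise ValueError("dump requires the exact backend")
        with open(path, "w") as out:
            for kmer in sorted(self.counts):
                out.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def load_tsv(cls, path: str | Path, k: int, canonical: bool = False) -> "KmerSpectrum":
        spec = cls(k=k, backend="exact", canonical=canonical)
        with open(path) as handle:
            for line in handle:
                kmer, count = line.split("\t")
                spec.add(kmer, int(count))
        return spec


def build_spectrum(
    reads: Iterable[ReadRecord],
    k: int,
    backend: str = "exact",
    canonical: bool = False,
    bloom_params: CountingBloomParams | None = None,
) -> KmerSpectrum:
    """Count every N-free k-mer instance across ``reads``.

    With ``canonical=True`` a k-mer and its reverse complement share one key
    (shotgun data, where read strand is arbitrary); amplicon data is
    strand-specific and uses ``canonical=False``.
    """
    if backend not in ("exact", "counting_bloom"):
        raise ValueError(f"unknown backend {backend!r}")
    if backend == "counting_bloom" and bloom_params is None:
        raise ValueError("bloom_params is required for the counting_bloom backend")
    if backend == "exact" and bloom_params is not None:
        raise ValueError("bloom_params given but backend is exact")
    spec = KmerSpectrum(k=k, backend=backend, canonical=canonical)
    if backend == "counting_bloom":
        spec.bloom = CountingBloomFilter(bloom_params)
    for read in reads:
        for kmer, _ in extract_kmers(read.sequence, k):
            spec.add(kmer)
    return spec
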