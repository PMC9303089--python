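from __future__ import annotations

import random

import pytest

from kspec.io_formats import ReadRecord
from kspec.spectrum import KmerSpectrum


def make_spectrum(counts: dict[str, int], k: int, canonical: bool = False) -> KmerSpectrum:
    """Exact spectrum with the given k-mer counts, for hand-built fixtures."""
    spec = KmerSpectrum(k=k, backend="exact", canonical=canonical)
    for kmer, count in counts.items():
        spec.add(kmer, count)
    return spec


def random_sequence(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1729)


@pytest.fixture
def backbone_reads() -> tuple[str, list[ReadRecord]]:
    """A 200 bp reference tiled by error-free reads at depth 10.

    Every reference k-mer (k <= 60) appears at least ~7 times, giving a
    solid background against which single planted errors stand out.
    """
    r = random.Random(7)
    genome = random_sequence(r, 200)
    reads = []
    idx = 0
    for _ in range(10):
        for start in range(0, 141, 10):
            reads.append(ReadRecord(f"b{idx}", genome[start : start + 60]))
            idx += 1
    return genome, reads
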