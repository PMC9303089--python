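"""Read simulation with exact ground truth.

Generates a random (or user-supplied) reference, samples fixed-length reads
at a target coverage depth — shotgun mode — or full-length amplicon reads
from a haplotype mixture, plants per-base substitution (optionally indel)
errors at a stated rate, and records every planted error as a TEF record.
Truth coordinates are on the read *as sequenced* (after reverse
complementing for minus-strand reads), so correctors and evaluators never
need to know the strand.

All randomness flows from a single integer seed through one
``numpy.random.Generator``, so every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import ReadRecord, TefEdit, TefRecord, emit_tef, write_fasta, write_fastq
from .spectrum import reverse_complement

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_reads",
    "simulate_amplicon",
]

_BASES = np.array(list("ACGT"))
DEFAULT_QUALITY = "I"  # Phred+33 Q40


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated dataset.

    ``coverage`` is mean depth per reference position (shotgun) or the
    number of full-length reads (amplicon).  ``substitution_rate`` and
    ``indel_rate`` are per-base probabilities; indels split evenly between
    insertions and deletions.
    """

    read_length: int = 100
    coverage: float = 30.0
    substitution_rate: float = 0.01
    indel_rate: float = 0.0
    paired: bool = False
    insert_size_mean: float = 300.0
    insert_size_sd: float = 30.0
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")


@dataclass
class SimulatedDataset:
    """Reads plus everything needed to score a corrector against them."""

    reference: str | list[str]
    reads: list[ReadRecord]
    truth: list[TefRecord]
    placements: list[tuple[int, str]]  # (ref_start, strand) per read
    truth_frequencies: dict[str, float] | None = None
    haplotype_of_read: list[int] = field(default_factory=list)

    @property
    def read_lengths(self) -> list[int]:
        return [len(r.sequence) for r in self.reads]

    def to_files(self, prefix: str | Path) -> dict[str, Path]:
        prefix = Path(prefix)
        refs = self.reference if isinstance(self.reference, list) else [self.reference]
        ref_records = [ReadRecord(f"ref_{i}", seq) for i, seq in enumerate(refs)]
        paths = {
            "fasta": prefix.with_suffix(".fasta"),
            "fastq": prefix.with_suffix(".fastq"),
            "tef": prefix.with_suffix(".tef"),
        }
        write_fasta(ref_records, paths["fasta"])
        write_fastq(self.reads, paths["fastq"])
        emit_tef(self.truth, paths["tef"])
        return paths


def simulate_genome(length: int, gc_content: float = 0.5, seed: int = 0) -> str:
    """Random i.i.d. genome with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    gc = gc_content / 2
    at = (1 - gc_content) / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])  # A, C, G, T
    return "".join(_BASES[idx])


def _plant_errors(
    sequence: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[TefEdit]]:
    """Apply substitution/indel errors; edits are in as-sequenced coordinates."""
    out: list[str] = []
    edits: list[TefEdit] = []
    for base in sequence:
        u = rng.random()
        # A deletion recorded at this position already exists when the
        # previous base was deleted; a second edit here would collide, so
        # this base is emitted untouched (probability ~ rate^2).
        if edits and edits[-1].edit_type == "deletion" and edits[-1].position == len(out):
            out.append(base)
            continue
        if u < config.substitution_rate:
            choices = [b for b in "ACGT" if b != base]
            wrong = choices[rng.integers(3)]
            edits.append(TefEdit(len(out), wrong, base, "substitution"))
            out.append(wrong)
        elif u < config.substitution_rate + config.indel_rate / 2:
            # deletion: the true base is missing before the next read base
            edits.append(TefEdit(len(out), "-", base, "deletion"))
        elif u < config.substitution_rate + config.indel_rate:
            # insertion: a spurious base precedes the true one
            spurious = "ACGT"[rng.integers(4)]
            edits.append(TefEdit(len(out), spurious, "-", "insertion"))
            out.append(spurious)
            out.append(base)
        else:
            out.append(base)
    return "".join(out), edits


def simulate_reads(genome: str, config: SimulationConfig) -> SimulatedDataset:
    """Uniformly sampled fixed-length shotgun reads with planted errors.

    The number of reads is ``round(coverage * len(genome) / read_length)``;
    start positions are uniform on the linear genome, strand is a fair coin,
    minus-strand fragments are reverse-complemented before errors are
    planted.  In paired mode reads come in pairs flanking an insert whose
    length is normal(insert_size_mean, insert_size_sd).
    """
    L = len(genome)
    rl = config.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds genome length {L}")
    rng = np.random.default_rng(config.seed)
    reads: list[ReadRecord] = []
    truth: list[TefRecord] = []
    placements: list[tuple[int, str]] = []

    def emit_read(start: int, strand: str) -> None:
        fragment = genome[start : start + rl]
        if strand == "-":
            fragment = reverse_complement(fragment)
        observed, edits = _plant_errors(fragment, config, rng)
        idx = len(reads)
        reads.append(
            ReadRecord(f"read_{idx}", observed, DEFAULT_QUALITY * len(observed))
        )
        truth.append(TefRecord(idx, tuple(edits)))
        placements.append((start, strand))

    if config.paired:
        n_pairs = round(config.coverage * L / rl / 2)
        for _ in range(n_pairs):
            insert = max(2 * rl, round(rng.normal(config.insert_size_mean, config.insert_size_sd)))
            insert = min(insert, L)
            start = int(rng.integers(0, L - insert + 1))
            emit_read(start, "+")
            emit_read(start + insert - rl, "-")
    else:
        n_reads = round(config.coverage * L / rl)
        for _ in range(n_reads):
            start = int(rng.integers(0, L - rl + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            emit_read(start, strand)
    return SimulatedDataset(genome, reads, truth, placements)


def simulate_amplicon(
    haplotypes: Sequence[str],
    frequencies: Sequence[float],
    coverage: float,
    config: SimulationConfig,
) -> SimulatedDataset:
    """Full-length amplicon reads drawn from a haplotype mixture.

    Each of the ``round(coverage)`` reads comes from haplotype ``h`` with
    probability ``frequencies[h]`` (all reads plus-strand: amplicon
    sequencing is strand-specific); errors are planted as in shotgun mode.
    """
    if not haplotypes:
        raise ValueError("empty haplotype set")
    if len(haplotypes) != len(frequencies):
        raise ValueError("haplotypes and frequencies differ in length")
    freqs = np.asarray(frequencies, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
        raise ValueError("frequencies must be non-negative and sum to 1")
    rng = np.random.default_rng(config.seed)
    n_reads = round(coverage)
    reads: list[ReadRecord] = []
    truth: list[TefRecord] = []
    placements: list[tuple[int, str]] = []
    hap_of_read: list[int] = []
    assignments = rng.choice(len(haplotypes), size=n_reads, p=freqs)
    for idx, h in enumerate(assignments):
        observed, edits = _plant_errors(haplotypes[h], config, rng)
        reads.append(ReadRecord(f"read_{idx}", observed, DEFAULT_QUALITY * len(observed)))
        truth.append(TefRecord(idx, tuple(edits)))
        placements.append((0, "+"))
        hap_of_read.append(int(h))
    truth_frequencies = {hap: float(freqs[i]) for i, hap in enumerate(haplotypes)}
    return SimulatedDataset(
        list(haplotypes), reads, truth, placements, truth_frequencies, hap_of_read
    )
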