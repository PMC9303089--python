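"""Amplicon postprocessing: collapse corrected reads into haplotypes.

After correction, reads from a deep-sequenced amplicon that share an exact
sequence are taken to represent the same haplotype; the read-count fraction
estimates that haplotype's population frequency.  Rows below the reporting
floor are aggregated into a single below-floor remainder so frequencies
always sum to one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .correction import CorrectionOutcome
from .io_formats import ReadRecord, write_fasta

__all__ = ["HaplotypeTable", "collapse_haplotypes"]

DEFAULT_MIN_FREQUENCY = 0.001


@dataclass
class HaplotypeTable:
    """Deduplicated haplotypes with counts and frequency estimates.

    ``table`` has columns (haplotype, count, frequency) sorted by descending
    count, ties broken lexicographically; ``remainder_frequency`` is the
    aggregated mass of haplotypes below ``min_frequency``.
    """

    table: pd.DataFrame
    total_reads: int
    min_frequency: float
    remainder_count: int

    @property
    def remainder_frequency(self) -> float:
        return self.remainder_count / self.total_reads if self.total_reads else 0.0

    def frequency_of(self, sequence: str) -> float:
        hits = self.table.loc[self.table["haplotype"] == sequence, "frequency"]
        return float(hits.iloc[0]) if len(hits) else 0.0

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            ReadRecord(f"hap_{rank + 1}_freq_{row.frequency:.6g}", row.haplotype)
            for rank, row in enumerate(self.table.itertuples())
        ]
        write_fasta(records, path)


def collapse_haplotypes(
    outcomes: Iterable[CorrectionOutcome] | Sequence[str],
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
) -> HaplotypeTable:
    """Exact-sequence deduplication of non-discarded corrected reads.

    Accepts correction outcomes (discarded reads are excluded) or raw
    sequence strings.  Frequency = count / total over retained reads.
    """
    sequences: list[str] = []
    for item in outcomes:
        if isinstance(item, str):
            sequences.append(item)
        elif item.status != "discarded":
            sequences.append(item.corrected_sequence)
    counts = Counter(sequences)
    total = len(sequences)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = []
    remainder = 0
    for seq, count in rows:
        freq = count / total
        if freq >= min_frequency:
            kept.append((seq, count, freq))
        else:
            remainder += count
    table = pd.DataFrame(kept, columns=["haplotype", "count", "frequency"])
    return HaplotypeTable(table, total, min_frequency, remainder)
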