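"""Reading and writing of reads (FASTA/FASTQ) and per-read error records (TEF).

All other modules exchange in-memory :class:`ReadRecord` / :class:`TefRecord`
objects; file formats only appear here.

The TEF (target error format) dialect used throughout the package is
tab-separated, one read per line::

    read_index  num_edits  {position observed true type}*num_edits

with ``type`` one of ``S`` (substitution), ``I`` (insertion), ``D``
(deletion) and positions 0-based on the read as sequenced.  For insertions
``observed`` is the inserted base and ``true`` is ``-``; for deletions
``observed`` is ``-`` and ``true`` is the missing base.  The dialect
round-trips byte-identically through :func:`parse_tef` / :func:`emit_tef`.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReadRecord",
    "TefEdit",
    "TefRecord",
    "FormatError",
    "parse_fastq",
    "parse_fasta",
    "write_fastq",
    "write_fasta",
    "parse_tef",
    "emit_tef",
]

_VALID_BASES = frozenset("ACGTN")
_EDIT_TYPES = {"S": "substitution", "I": "insertion", "D": "deletion"}
_EDIT_CODES = {v: k for k, v in _EDIT_TYPES.items()}


class FormatError(ValueError):
    """Raised when an input file violates its format."""


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read.

    Parameters
    ----------
    read_id:
        Identifier from the FASTA/FASTQ header.
    sequence:
        Upper-case bases over ``{A, C, G, T, N}``.
    qualities:
        Phred+33 quality string of the same length, or ``None`` for FASTA
        input.
    """

    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True, order=True)
class TefEdit:
    """One base-level difference between an observed read and its true read."""

    position: int
    observed: str
    true: str
    edit_type: str = "substitution"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise FormatError(f"negative edit position {self.position}")
        if self.edit_type not in _EDIT_CODES:
            raise FormatError(f"unknown edit type {self.edit_type!r}")
        if self.edit_type == "substitution" and self.observed == self.true:
            raise FormatError(
                f"substitution at {self.position} with observed == true ({self.observed!r})"
            )


@dataclass(frozen=True)
class TefRecord:
    """Ground-truth or applied edits for one read, keyed by file ordinal."""

    read_index: int
    edits: tuple[TefEdit, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.read_index < 0:
            raise FormatError(f"negative read index {self.read_index}")
        object.__setattr__(self, "edits", tuple(self.edits))
        positions = [e.position for e in self.edits]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise FormatError(
                f"read {self.read_index}: edit positions not strictly increasing: {positions}"
            )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open ``path`` transparently decompressing gzip input."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(path, "rb"))  # type: ignore[arg-type]
    return open(path, mode)


def parse_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a (possibly gzipped) 4-line FASTQ file.

    Records are returned in file order; their 0-based ordinal is the
    ``read_index`` used by TEF records.  Malformed records raise
    :class:`FormatError` naming the offending line number.
    """
    records: list[ReadRecord] = []
    with _open_text(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ record starting at line {4 * (len(lines) // 4) + 1}")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not header.startswith("@"):
            raise FormatError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{lineno + 2}: expected '+' separator, got {plus[:20]!r}")
        seq = seq.upper()
        if not seq or set(seq) - _VALID_BASES:
            raise FormatError(f"{path}:{lineno + 1}: invalid sequence characters")
        if len(qual) != len(seq):
            raise FormatError(
                f"{path}:{lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        records.append(ReadRecord(header[1:].split()[0], seq, qual))
    return records


def parse_fasta(path: str | Path) -> list[ReadRecord]:
    """Parse a (possibly gzipped) FASTA file into quality-less records."""
    with _open_text(path) as handle:
        return [
            ReadRecord(rec.id, str(rec.seq).upper(), None)
            for rec in SeqIO.parse(handle, "fasta")
        ]


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            qual = rec.qualities if rec.qualities is not None else "I" * len(rec.sequence)
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def write_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.read_id, description="") for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _parse_tef_line(line: str, lineno: int, source: str) -> TefRecord:
    fields = line.split("\t")
    try:
        read_index = int(fields[0])
        num_edits = int(fields[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{source}:{lineno}: bad header fields {fields[:2]!r}") from exc
    expected = 2 + 4 * num_edits
    if len(fields) != expected:
        raise FormatError(
            f"{source}:{lineno}: expected {expected} fields for {num_edits} edits, got {len(fields)}"
        )
    edits = []
    for j in range(num_edits):
        pos_s, obs, true, code = fields[2 + 4 * j : 6 + 4 * j]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise FormatError(f"{source}:{lineno}: non-integer position {pos_s!r}") from exc
        if code not in _EDIT_TYPES:
            raise FormatError(f"{source}:{lineno}: unknown edit type code {code!r}")
        edits.append(TefEdit(pos, obs, true, _EDIT_TYPES[code]))
    return TefRecord(read_index, tuple(edits))


def parse_tef(path: str | Path) -> list[TefRecord]:
    """Parse a TEF file (dialect described in the module docstring)."""
    records = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            records.append(_parse_tef_line(line, lineno, str(path)))
    return records


def tef_line(record: TefRecord) -> str:
    parts = [str(record.read_index), str(len(record.edits))]
    for e in record.edits:
        parts.extend([str(e.position), e.observed, e.true, _EDIT_CODES[e.edit_type]])
    return "\t".join(parts)


def emit_tef(records: Sequence[TefRecord], path: str | Path) -> None:
    """Write TEF records; round-trips byte-identically with :func:`parse_tef`."""
    with open(path, "w") as out:
        for rec in records:
            out.write(tef_line(rec) + "\n")
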