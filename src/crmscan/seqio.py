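"""Sequence and interval I/O.

Plain-text formats only: multi-record FASTA (case preserved; lowercase means
repeat-masked) and BED3-BED6. Coordinates are 0-based half-open throughout,
the BED convention; any 1-based dialect must be converted at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

SEQ_ALPHABET = set("ACGTNacgtn")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case (masking state)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence; lowercase letters are repeat-masked positions."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        bad = set(self.seq) - SEQ_ALPHABET
        if bad:
            raise ValueError(f"illegal characters in sequence {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def masked(self) -> "SequenceRecord":
        """Copy with repeat-masked (lowercase) positions replaced by N."""
        seq = "".join("N" if c.islower() else c for c in self.seq)
        return SequenceRecord(self.id, seq)


@dataclass
class GenomicInterval:
    """0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> int:
        """Length of the overlap with `other` (0 when disjoint or trans-chromosomal)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a multi-record FASTA, preserving case.

    Raises FormatError on an empty file or text preceding the first header.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if not stripped:
        raise FormatError(f"empty FASTA file: {path}")
    if not stripped.startswith(">"):
        raise FormatError(f"FASTA file does not start with a header: {path}")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not rec.id:
            raise FormatError(f"record with empty header in {path}")
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3-BED6; optional name (col 4) and strand (col 6) are honored."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def extract_sequence(
    genome: list[SequenceRecord],
    iv: GenomicInterval,
    mask_policy: str = "keep",
) -> SequenceRecord:
    """Extract the interval's sequence from a genome.

    Reverse-complemented for "-" strand intervals. mask_policy is one of
    "keep" (lowercase preserved), "to_N" (masked positions become N) or
    "uppercase" (masking discarded).
    """
    if mask_policy not in {"keep", "to_N", "uppercase"}:
        raise ValueError(f"unknown mask_policy {mask_policy!r}")
    by_id = {rec.id: rec for rec in genome}
    if iv.chrom not in by_id:
        raise LookupError(f"chromosome {iv.chrom!r} not in genome")
    chrom = by_id[iv.chrom]
    if iv.end > len(chrom.seq):
        raise LookupError(f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end {len(chrom.seq)}")
    sub = chrom.seq[iv.start : iv.end]
    if iv.strand == "-":
        sub = reverse_complement(sub)
    if mask_policy == "to_N":
        sub = "".join("N" if c.islower() else c for c in sub)
    elif mask_policy == "uppercase":
        sub = sub.upper()
    name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
    return SequenceRecord(name, sub)
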