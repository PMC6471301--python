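"""Genomic intervals and BED6 I/O.

All coordinates are 0-based half-open, matching native BED. Conversions for
1-based formats (SAM) happen at the format boundary, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A named, optionally stranded region on a reference sequence."""

    reference: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.reference}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, reference: str, start: int, end: int) -> bool:
        """True when [start, end) shares at least one base with this interval."""
        return (
            reference == self.reference and start < self.end and self.start < end
        )

    def contains_point(self, reference: str, position: int) -> bool:
        return reference == self.reference and self.start <= position < self.end


def overlaps_any(
    intervals: Iterable[GenomicInterval], reference: str, start: int, end: int
) -> bool:
    return any(iv.overlaps(reference, start, end) for iv in intervals)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per reference (strand ignored)."""
    merged: list[GenomicInterval] = []
    by_ref: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_ref.setdefault(iv.reference, []).append(iv)
    for ref in sorted(by_ref):
        ivs = sorted(by_ref[ref], key=lambda iv: (iv.start, iv.end))
        cur = ivs[0]
        for iv in ivs[1:]:
            if iv.start <= cur.end:
                if iv.end > cur.end:
                    cur = replace(cur, end=iv.end)
            else:
                merged.append(cur)
                cur = iv
        merged.append(cur)
    return merged


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total non-redundant length after merging."""
    return sum(iv.length for iv in merge_intervals(intervals)) if intervals else 0


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3-6 columns) into intervals; score column is discarded."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name, strand)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.reference}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )
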