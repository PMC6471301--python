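"""FASTQ reading and collapsing to unique small-RNA sequences.

Abundance arithmetic everywhere downstream operates on collapsed reads: one
record per distinct sequence with its copy count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class CollapsedRead:
    """A unique small-RNA sequence with its copy count."""

    id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not set(self.sequence) <= DNA_ALPHABET:
            raise ValueError(f"non-DNA characters in {self.sequence!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _iter_fastq(path: str | Path) -> Iterator[str]:
    parser = SeqIO.parse(str(path), "fastq")
    i = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ near record {i + 1}: {exc}") from exc
        i += 1
        yield str(record.seq).upper()


def collapse(
    reads: str | Path | Iterable[str],
    min_len: int = 19,
    max_len: int = 29,
) -> list[CollapsedRead]:
    """Collapse a FASTQ file (or an iterable of sequences) to unique reads.

    Reads outside [min_len, max_len] are discarded (the library's minimal
    length filter is >18 nt, hence the default 19). Reads containing N are
    dropped and counted in the log. Counts of the returned records sum to
    the number of retained input reads. Record ids are assigned in sequence
    order (lexicographic), so the result is independent of input order.
    """
    if isinstance(reads, (str, Path)):
        seqs: Iterable[str] = _iter_fastq(reads)
    else:
        seqs = (s.upper() for s in reads)

    tally: dict[str, int] = {}
    n_len_filtered = 0
    n_ambiguous = 0
    n_kept = 0
    for seq in seqs:
        if not min_len <= len(seq) <= max_len:
            n_len_filtered += 1
            continue
        if "N" in seq:
            n_ambiguous += 1
            continue
        tally[seq] = tally.get(seq, 0) + 1
        n_kept += 1

    if n_ambiguous:
        logger.info("dropped %d reads containing N", n_ambiguous)
    logger.info(
        "collapse: kept %d reads (%d unique), length-filtered %d",
        n_kept,
        len(tally),
        n_len_filtered,
    )
    return [
        CollapsedRead(id=f"seq{i:06d}", sequence=seq, count=count)
        for i, (seq, count) in enumerate(sorted(tally.items()))
    ]


def total_count(reads: Iterable[CollapsedRead]) -> int:
    return sum(r.count for r in reads)


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path: str | Path) -> None:
    """FASTA with ``id_count`` headers, the conventional collapsed format."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}_{r.count}\n{r.sequence}\n")
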