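"""Bounded-mismatch read placement on desk-scale references.

The mapper reports EVERY placement of a read, on either strand, whose
Hamming distance to the reference window is at most the configured bound
(substitutions only, no indels — appropriate for 19-29 nt reads, and the
two regimes used in practice are 0 mismatches against genomic references
and 0-3 against TE consensus sequences). ``N`` in a read or reference never
matches any base. For genome-scale work alignments from an external aligner
can be imported from SAM instead; coordinates are converted to 0-based
half-open at that boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .reads import CollapsedRead
from .simulate import reverse_complement

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class AlignmentRecord:
    """One placement of a collapsed read on a named reference.

    ``n_hits`` is the total number of placements of the read across the
    whole reference set at the chosen mismatch bound; a read is "uniquely
    mapped" iff n_hits == 1. ``count`` carries the read's copy count so that
    downstream statistics stay count-weighted.
    """

    read_id: str
    reference: str
    start: int
    end: int
    strand: str
    mismatches: int
    n_hits: int
    count: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid alignment interval")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.n_hits < 1 or self.count < 1 or self.mismatches < 0:
            raise ValueError("n_hits/count must be >= 1, mismatches >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def unique(self) -> bool:
        return self.n_hits == 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_N_BYTE = ord("N")


def _exact_hits(ref: str, query: str) -> list[int]:
    """All exact occurrences of query in ref (N never matches)."""
    if "N" in query:
        return []
    hits = []
    pos = ref.find(query)
    while pos != -1:
        hits.append(pos)
        pos = ref.find(query, pos + 1)
    # str.find treats N as a literal character; reject windows containing N
    if "N" in ref:
        hits = [h for h in hits if "N" not in ref[h : h + len(query)]]
    return hits


def _hamming_hits(
    ref_arr: np.ndarray, ref_n: np.ndarray, query: str, max_mm: int
) -> list[tuple[int, int]]:
    """(position, mismatches) for all windows within the Hamming bound."""
    L = len(query)
    if L > len(ref_arr):
        return []
    q = _encode(query)
    q_is_n = q == _N_BYTE
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    mm = (windows != q).sum(axis=1)
    if q_is_n.any():  # read N must mismatch even an N in the reference
        n_windows = np.lib.stride_tricks.sliding_window_view(ref_n, L)
        mm = mm + (n_windows & q_is_n).sum(axis=1)
    positions = np.nonzero(mm <= max_mm)[0]
    return [(int(p), int(mm[p])) for p in positions]


def align(
    reads: Sequence[CollapsedRead],
    references: Mapping[str, str],
    max_mismatch: int = 0,
) -> list[AlignmentRecord]:
    """Place every read on every reference, both strands, within the bound.

    Returns records sorted by (reference, start, strand, read_id) with
    ``n_hits`` set to each read's total placement count over the whole set.
    """
    if not references:
        raise ValueError("empty reference set")
    if max_mismatch not in (0, 1, 2, 3):
        raise ValueError("max_mismatch must be in {0, 1, 2, 3}")

    prepared = {}
    for name, seq in references.items():
        seq = seq.upper()
        arr = _encode(seq)
        prepared[name] = (seq, arr, arr == _N_BYTE)

    raw: list[AlignmentRecord] = []
    hits_per_read: dict[str, int] = {}
    for read in reads:
        fwd = read.sequence
        rev = reverse_complement(fwd)
        n_hits = 0
        for name, (seq, arr, is_n) in prepared.items():
            for strand, query in (("+", fwd), ("-", rev)):
                if max_mismatch == 0:
                    found = [(p, 0) for p in _exact_hits(seq, query)]
                else:
                    found = _hamming_hits(arr, is_n, query, max_mismatch)
                for pos, mm in found:
                    raw.append(
                        AlignmentRecord(
                            read_id=read.id,
                            reference=name,
                            start=pos,
                            end=pos + len(query),
                            strand=strand,
                            mismatches=mm,
                            n_hits=1,  # patched below
                            count=read.count,
                        )
                    )
                    n_hits += 1
        if n_hits:
            hits_per_read[read.id] = n_hits

    out = [replace(a, n_hits=hits_per_read[a.read_id]) for a in raw]
    out.sort(key=lambda a: (a.reference, a.start, a.strand, a.read_id))
    return out


# ---------------------------------------------------------------------------
# SAM interop


def export_sam(
    alignments: Sequence[AlignmentRecord],
    reads: Mapping[str, CollapsedRead],
    references: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write alignments as plain SAM with NM and NH tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in references.items()],
    }
    ref_index = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seq = reads[a.read_id].sequence
            seg.flag = 16 if a.strand == "-" else 0
            # SAM stores the reference-strand sequence
            seg.query_sequence = (
                reverse_complement(seq) if a.strand == "-" else seq
            )
            seg.reference_id = ref_index[a.reference]
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.length}M"
            seg.set_tag("NM", a.mismatches)
            seg.set_tag("NH", a.n_hits)
            out.write(seg)


def import_sam(
    path: str | Path,
    references: Mapping[str, str],
    counts: Mapping[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Read SAM/BAM alignments into records (0-based half-open, NM tag).

    ``n_hits`` is taken from the NH tag when present, otherwise from the
    per-read record count in the file. ``counts`` maps read id to copy
    count (defaults to 1, or to a trailing ``_<count>`` suffix in the read
    name, the conventional collapsed-read encoding). Unmapped records are
    skipped; a reference name absent from ``references`` is an error.
    """
    per_read: dict[str, int] = {}
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.reference_name not in references:
                raise ValueError(
                    f"SAM reference {rec.reference_name!r} not in reference set"
                )
            rows.append({
                "_name": rec.query_name,
                "_ref": rec.reference_name,
                "_start": rec.reference_start,
                "_end": rec.reference_end,
                "_rev": rec.is_reverse,
                "_nm": rec.get_tag("NM") if rec.has_tag("NM") else 0,
                "_nh": rec.get_tag("NH") if rec.has_tag("NH") else None,
            })
            per_read[rec.query_name] = per_read.get(rec.query_name, 0) + 1

    def _count(name: str) -> int:
        if counts is not None and name in counts:
            return counts[name]
        if "_" in name:
            tail = name.rsplit("_", 1)[1]
            if tail.isdigit():
                return int(tail)
        return 1

    out = [
        AlignmentRecord(
            read_id=r["_name"],
            reference=r["_ref"],
            start=r["_start"],
            end=r["_end"],
            strand="-" if r["_rev"] else "+",
            mismatches=int(r["_nm"]),
            n_hits=int(r["_nh"]) if r["_nh"] is not None else per_read[r["_name"]],
            count=_count(r["_name"]),
        )
        for r in rows
    ]
    out.sort(key=lambda a: (a.reference, a.start, a.strand, a.read_id))
    return out


def alignments_to_tsv(alignments: Sequence[AlignmentRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([a.__dict__ for a in alignments]).to_csv(path, sep="\t", index=False)
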