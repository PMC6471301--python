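"""Abundance and profile statistics for small-RNA libraries.

Size classes follow the standard ovarian small-RNA convention: 24-29 nt
reads are counted as piRNAs, 21 nt reads as endo-siRNAs, everything else in
the 19-29 nt window is "other". All abundances are reported in RPM (reads
per million mapped reads); the denominator is the library's total mapped
19-29 nt count, chosen for cross-library comparability.

Multi-mapper policy is set per analysis: ``unique`` keeps only reads with a
single placement (used for the transgene-flank statistic), ``weighted``
spreads each read's count uniformly over its placements with weight
count/n_hits (used for TE-consensus abundance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, overlaps_any
from .mapping import AlignmentRecord
from .reads import CollapsedRead

PIRNA_LENGTHS = tuple(range(24, 30))
SIRNA_LENGTH = 21


def classify(length: int) -> str:
    """Size-class a read: 24-29 nt piRNA, 21 nt siRNA, otherwise 'other'."""
    if 24 <= length <= 29:
        return "piRNA"
    if length == SIRNA_LENGTH:
        return "siRNA"
    return "other"


@dataclass(frozen=True)
class LibraryStats:
    """Mapped-library summary: the RPM denominator and the size table."""

    name: str
    total_mapped: float
    length_strand_table: pd.DataFrame  # index: length 19..29, columns: +, -

    @classmethod
    def from_alignments(
        cls, alignments: Sequence[AlignmentRecord], name: str = "library"
    ) -> "LibraryStats":
        """Each placement contributes count/n_hits, so every mapped read is
        counted exactly once in total."""
        table = pd.DataFrame(
            0.0, index=range(19, 30), columns=["+", "-"]
        )
        for a in alignments:
            if a.length in table.index:
                table.loc[a.length, a.strand] += a.count / a.n_hits
        return cls(name=name, total_mapped=float(table.values.sum()),
                   length_strand_table=table)


def rpm(count: float, library_total: float) -> float:
    """Reads-per-million normalization."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return count * 1e6 / library_total


def _weight(a: AlignmentRecord, policy: str) -> float:
    if policy == "unique":
        return float(a.count) if a.n_hits == 1 else 0.0
    if policy == "weighted":
        return a.count / a.n_hits
    raise ValueError(f"unknown multi-mapper policy {policy!r}")


def u1_bias(
    alignments: Sequence[AlignmentRecord],
    reads: Mapping[str, CollapsedRead],
    lengths: Iterable[int] = PIRNA_LENGTHS,
    strand: str | None = None,
    exclude: Sequence[GenomicInterval] = (),
) -> float:
    """Count-weighted fraction of reads whose 5' base is uridine (T).

    The read's own first base IS its 5' base regardless of strand (the
    sequenced read is already the template-corrected small RNA). Reads whose
    placement overlaps any exclusion interval by >= 1 bp are removed first;
    returns NaN when nothing is retained.
    """
    lengths = set(lengths)
    num = 0.0
    den = 0.0
    for a in alignments:
        if a.length not in lengths:
            continue
        if strand is not None and a.strand != strand:
            continue
        if exclude and overlaps_any(exclude, a.reference, a.start, a.end):
            continue
        w = a.count / a.n_hits
        den += w
        if reads[a.read_id].sequence[0] == "T":
            num += w
    return num / den if den > 0 else float("nan")


def coverage_profile(
    alignments: Sequence[AlignmentRecord],
    interval: GenomicInterval,
    library_total: float,
    strand: str | None = None,
    policy: str = "weighted",
) -> np.ndarray:
    """Per-base RPM vector over ``interval`` (length == interval.length)."""
    profile = np.zeros(interval.length)
    for a in alignments:
        if a.reference != interval.reference:
            continue
        if strand is not None and a.strand != strand:
            continue
        w = _weight(a, policy)
        if w == 0.0:
            continue
        lo = max(a.start, interval.start) - interval.start
        hi = min(a.end, interval.end) - interval.start
        if lo < hi:
            profile[lo:hi] += w
    return profile * 1e6 / library_total


@dataclass(frozen=True)
class AbundanceRecord:
    feature: str
    sense_rpm: float
    antisense_rpm: float
    size_class: str = "piRNA"

    def __post_init__(self) -> None:
        if self.sense_rpm < 0 or self.antisense_rpm < 0:
            raise ValueError("RPM must be >= 0")


def flanking_abundance(
    alignments: Sequence[AlignmentRecord],
    insertion: GenomicInterval,
    library_total: float,
    window: int = 10000,
    policy: str = "unique",
    size_class: str = "piRNA",
) -> AbundanceRecord:
    """piRNA abundance in the window flanking the 3' end of a transgene.

    ``insertion`` marks the insertion point with the transgene orientation
    in its strand field; the 10-kb window extends 3' of the transgene, i.e.
    downstream on the genomic strand the transgene occupies. Unique-only by
    default: multi-mappers would blur a locus-specific statistic. Reads
    overlapping the window by >= 1 bp are counted, per genomic strand.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if insertion.strand == "-":
        lo, hi = insertion.start - window, insertion.start
    else:
        lo, hi = insertion.start, insertion.start + window
    lo = max(lo, 0)
    per_strand = {"+": 0.0, "-": 0.0}
    for a in alignments:
        if a.reference != insertion.reference:
            continue
        if classify(a.length) != size_class:
            continue
        if a.start < hi and lo < a.end:
            per_strand[a.strand] += _weight(a, policy)
    return AbundanceRecord(
        feature=f"{insertion.reference}:{lo}-{hi}",
        sense_rpm=rpm(per_strand["+"], library_total),
        antisense_rpm=rpm(per_strand["-"], library_total),
        size_class=size_class,
    )


def feature_rpm_table(
    alignments: Sequence[AlignmentRecord],
    library_total: float,
    policy: str = "weighted",
    size_class: str | None = "piRNA",
) -> pd.DataFrame:
    """Per-reference sense/antisense RPM table (reference name = feature)."""
    acc: dict[str, dict[str, float]] = {}
    for a in alignments:
        if size_class is not None and classify(a.length) != size_class:
            continue
        w = _weight(a, policy)
        if w == 0.0:
            continue
        acc.setdefault(a.reference, {"+": 0.0, "-": 0.0})[a.strand] += w
    rows = [
        {
            "feature": feat,
            "sense_rpm": rpm(v["+"], library_total),
            "antisense_rpm": rpm(v["-"], library_total),
            "total_rpm": rpm(v["+"] + v["-"], library_total),
        }
        for feat, v in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["feature", "sense_rpm", "antisense_rpm", "total_rpm"])


def te_family_table(
    alignments_a: Sequence[AlignmentRecord],
    alignments_b: Sequence[AlignmentRecord],
    total_a: float,
    total_b: float,
    pseudo_rpm: float = 1.0,
    size_class: str = "piRNA",
) -> pd.DataFrame:
    """Per-TE-family RPM in two libraries with fold changes.

    Multi-mappers are weight-shared (count/n_hits) — reads from repeated TE
    fragments must not be double-counted across families. Fold change is
    (RPM_b + c)/(RPM_a + c) with pseudo-RPM c, so families absent from one
    library still get a finite, conservative fold.
    """
    ta = feature_rpm_table(alignments_a, total_a, "weighted", size_class)
    tb = feature_rpm_table(alignments_b, total_b, "weighted", size_class)
    merged = (
        ta.set_index("feature")[["total_rpm"]]
        .rename(columns={"total_rpm": "rpm_a"})
        .join(
            tb.set_index("feature")[["total_rpm"]].rename(
                columns={"total_rpm": "rpm_b"}
            ),
            how="outer",
        )
        .astype(float)
        .fillna(0.0)
        .reset_index()
    )
    merged["fold_change"] = (merged["rpm_b"] + pseudo_rpm) / (
        merged["rpm_a"] + pseudo_rpm
    )
    merged["log2_fold_change"] = np.log2(merged["fold_change"])
    merged["log2_rpm_a"] = np.log2(merged["rpm_a"] + pseudo_rpm)
    merged["log2_rpm_b"] = np.log2(merged["rpm_b"] + pseudo_rpm)
    return merged


def genic_gain_calls(
    table: pd.DataFrame,
    t_low: float = 0.5,
    t_high: float = 5.0,
    t_fold: float = 10.0,
    pseudo_rpm: float = 1.0,
) -> pd.DataFrame:
    """Flag genes that gain piRNAs in condition B while silent in A.

    ``table`` needs columns gene, strand, rpm_a, rpm_b; a row is flagged
    when rpm_a < t_low, rpm_b >= t_high and the pseudo-counted fold reaches
    t_fold. Thresholds are deliberately configurable — there is no field
    convention for "de novo genic piRNA production".
    """
    t = table.copy()
    t["fold_change"] = (t["rpm_b"] + pseudo_rpm) / (t["rpm_a"] + pseudo_rpm)
    t["flagged"] = (
        (t["rpm_a"] < t_low)
        & (t["rpm_b"] >= t_high)
        & (t["fold_change"] >= t_fold)
    )
    return t


def export_bedgraph(
    profile: np.ndarray, interval: GenomicInterval, path
) -> None:
    """Write a per-base profile as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        i = 0
        n = len(profile)
        while i < n:
            j = i
            while j + 1 < n and profile[j + 1] == profile[i]:
                j += 1
            if profile[i] != 0.0:
                fh.write(
                    f"{interval.reference}\t{interval.start + i}\t"
                    f"{interval.start + j + 1}\t{profile[i]:g}\n"
                )
            i = j + 1
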