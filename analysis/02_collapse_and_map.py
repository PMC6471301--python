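#!/usr/bin/env python
"""Collapse each simulated library and map it at 0 mismatches.

Reads results/sim/<condition>/ from step 01; writes alignments.sam, the
per-length/strand size table and per-feature RPM under the same directory.
The log line per condition reports the RPM denominator (total mapped
19-29-nt reads), which every later abundance statistic uses.
"""

from pathlib import Path

from pyfaidx import Fasta

from pirnakit.mapping import align, export_sam
from pirnakit.reads import collapse, total_count
from pirnakit.stats import LibraryStats, feature_rpm_table

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    for condition in ("insulated", "restored"):
        outdir = SIM / condition
        fa = Fasta(str(outdir / "references.fasta"), as_raw=True, sequence_always_upper=True)
        references = {name: str(fa[name][:]) for name in fa.keys()}
        collapsed = collapse(outdir / "reads.fastq")
        alignments = align(collapsed, references, max_mismatch=0)
        export_sam(
            alignments, {r.id: r for r in collapsed}, references,
            outdir / "alignments.sam",
        )
        lib = LibraryStats.from_alignments(alignments, name=condition)
        lib.length_strand_table.to_csv(outdir / "length_strand_table.tsv", sep="\t")
        feature_rpm_table(alignments, lib.total_mapped, size_class=None).to_csv(
            outdir / "feature_rpm.tsv", sep="\t", index=False
        )
        print(
            f"{condition}: {total_count(collapsed)} retained reads "
            f"({len(collapsed)} unique), RPM denominator {lib.total_mapped:.0f}"
        )


if __name__ == "__main__":
    main()
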