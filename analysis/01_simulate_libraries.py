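#!/usr/bin/env python
"""Simulate the study's small-RNA libraries with known ground truth.

Two ovarian-library conditions over one 30-kb dual-strand piRNA cluster
carrying an insulator-bearing transgene insertion at 10 kb:

* ``insulated``  — the insertion suppresses piRNA precursor transcription
  across its 10-kb 3' flank (residual 10%), the wild-type situation for a
  Su(Hw)-bound transgene;
* ``restored``   — no suppression, the situation after loss of insulator
  binding (the su(Hw) mutant), with an active ping-pong cycle.

Writes FASTA/BED/FASTQ/truth under results/sim/<condition>/.
"""

from pathlib import Path

from pirnakit.intervals import GenomicInterval
from pirnakit.simulate import (
    MotifInsertion,
    ReferenceSpec,
    SimulationConfig,
    SuppressionZone,
    TransgeneInsertion,
    generate_reference,
    simulate_reads,
    write_annotations,
    write_fasta,
    write_fastq,
    write_truth,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 20260925
INSERTION_POINT = 10000

REFERENCES = [
    ReferenceSpec("cluster42", 30000, "cluster"),
    ReferenceSpec("TART-B", 2000, "TE_consensus"),
]
MOTIFS = [
    MotifInsertion("cluster42", INSERTION_POINT + 50, "TGCATACTTCTGC"),
]


def build_config(condition: str) -> SimulationConfig:
    suppressed = condition == "insulated"
    return SimulationConfig(
        seed=SEED if suppressed else SEED + 1,
        reference_spec=REFERENCES,
        motif_insertions=MOTIFS,
        transgene_insertion=TransgeneInsertion("cluster42", INSERTION_POINT, "+"),
        n_reads=20000,
        pingpong_fraction=0.0 if suppressed else 0.3,
        read_sources=["cluster42"],
        suppression_zones=(
            [
                SuppressionZone(
                    GenomicInterval(
                        "cluster42", INSERTION_POINT, INSERTION_POINT + 10000
                    ),
                    0.1,
                )
            ]
            if suppressed
            else []
        ),
    )


def main() -> None:
    for condition in ("insulated", "restored"):
        outdir = OUT / condition
        outdir.mkdir(parents=True, exist_ok=True)
        config = build_config(condition)
        references, annotations = generate_reference(config)
        reads, truth = simulate_reads(config, references)
        write_fasta(references, outdir / "references.fasta")
        write_annotations(annotations, outdir)
        write_fastq(reads, outdir / "reads.fastq")
        write_truth(truth, outdir / "truth.tsv")
        config.to_yaml(outdir / "config.yaml")
        print(
            f"{condition}: {len(reads)} reads "
            f"({truth['is_pingpong_responder'].mean():.1%} ping-pong responders), "
            f"written to {outdir}"
        )


if __name__ == "__main__":
    main()
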