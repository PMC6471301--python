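"""End-to-end convenience workflows shared by drivers, tests and scripts."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intervals import GenomicInterval
from .mapping import AlignmentRecord, align
from .reads import CollapsedRead, collapse
from .simulate import SimulationConfig, generate_reference, simulate_reads
from .stats import LibraryStats


@dataclass
class MappedLibrary:
    """A simulated library taken through collapse and 0-mm mapping."""

    references: dict[str, str]
    annotations: list[GenomicInterval]
    truth: pd.DataFrame
    collapsed: list[CollapsedRead]
    alignments: list[AlignmentRecord]
    library: LibraryStats

    @property
    def reads_by_id(self) -> dict[str, CollapsedRead]:
        return {r.id: r for r in self.collapsed}

    def annotation(self, name: str) -> GenomicInterval:
        matches = [iv for iv in self.annotations if iv.name == name]
        if len(matches) != 1:
            raise ValueError(f"expected one {name!r} annotation, found {len(matches)}")
        return matches[0]


def simulate_and_map(
    config: SimulationConfig, max_mismatch: int = 0
) -> MappedLibrary:
    """simulate -> collapse -> align, the backbone of every synthetic run."""
    references, annotations = generate_reference(config)
    reads, truth = simulate_reads(config, references)
    collapsed = collapse([seq for _, seq in reads])
    alignments = align(collapsed, references, max_mismatch=max_mismatch)
    library = LibraryStats.from_alignments(alignments)
    return MappedLibrary(
        references=references,
        annotations=annotations,
        truth=truth,
        collapsed=collapsed,
        alignments=alignments,
        library=library,
    )
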