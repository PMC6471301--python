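"""Shared fixtures: small synthetic references and libraries."""

from __future__ import annotations

import numpy as np
import pytest

from pirnakit.reads import CollapsedRead
from pirnakit.simulate import (
    ReferenceSpec,
    SimulationConfig,
    generate_reference,
    simulate_reads,
)


@pytest.fixture(scope="session")
def cluster_config() -> SimulationConfig:
    """One 10-kb dual-strand cluster, defaults otherwise."""
    return SimulationConfig(
        seed=7,
        reference_spec=[ReferenceSpec("cluster42", 10000, "cluster")],
        n_reads=2000,
    )


@pytest.fixture(scope="session")
def cluster_reference(cluster_config):
    references, annotations = generate_reference(cluster_config)
    return references, annotations


@pytest.fixture(scope="session")
def cluster_library(cluster_config, cluster_reference):
    references, _ = cluster_reference
    reads, truth = simulate_reads(cluster_config, references)
    return reads, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def random_reads(
    rng: np.random.Generator, n: int, lengths=(24, 25, 26, 27)
) -> list[CollapsedRead]:
    """n random collapsed reads with random counts (may collide: counts merged)."""
    tally: dict[str, int] = {}
    for _ in range(n):
        L = int(rng.choice(lengths))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        tally[seq] = tally.get(seq, 0) + int(rng.integers(1, 4))
    return [
        CollapsedRead(id=f"seq{i:06d}", sequence=s, count=c)
        for i, (s, c) in enumerate(sorted(tally.items()))
    ]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
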