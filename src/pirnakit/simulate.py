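"""Synthetic small-RNA libraries with known ground truth.

The generator emulates the statistical structure of an ovarian small-RNA
library from a piRNA-cluster locus: read lengths peaked at 24-29 nt with an
optional 21-nt siRNA component, a tunable 5'-uridine (1U) bias per strand,
a tunable fraction of sense/antisense read pairs whose 5' ends overlap by
exactly 10 nt (the ping-pong signature), strand asymmetry, multi-mapping
reads from transposon fragments embedded in several references, and local
suppression zones that model an insulator-bearing transgene insertion
blocking precursor transcription.

Every run is driven by one integer seed through a single numpy Generator;
fixed seed implies byte-identical FASTA/BED/FASTQ/TSV outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, write_bed

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: read-length spectrum used by default: dominant 24-29 nt piRNA peak with a
#: minor 21-nt endo-siRNA component, roughly the shape of an ovarian library
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    21: 0.10,
    24: 0.10,
    25: 0.20,
    26: 0.25,
    27: 0.20,
    28: 0.10,
    29: 0.05,
}

VALID_ROLES = ("cluster", "gene", "TE_consensus", "transgene", "neutral")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSpec:
    name: str
    length: int
    role: str

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown reference role {self.role!r}")
        if self.length <= 0:
            raise ValueError(f"reference {self.name}: length must be positive")


@dataclass(frozen=True)
class MotifInsertion:
    reference: str
    position: int
    motif: str


@dataclass(frozen=True)
class TEEmbedding:
    """Copy a TE-consensus reference verbatim into a host reference.

    Embeddings are what create genuine multi-mapping reads: a read drawn from
    the embedded fragment aligns both to the host locus and to the consensus.
    """

    te_name: str
    reference: str
    position: int


@dataclass(frozen=True)
class TransgeneInsertion:
    reference: str
    position: int
    orientation: str  # "+" or "-", the genomic strand the transgene sits on

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("transgene orientation must be '+' or '-'")


@dataclass(frozen=True)
class SuppressionZone:
    interval: GenomicInterval
    residual_fraction: float


@dataclass
class SimulationConfig:
    """All knobs of one synthetic library, validated on construction."""

    seed: int = 0
    reference_spec: list[ReferenceSpec] = field(default_factory=list)
    motif_insertions: list[MotifInsertion] = field(default_factory=list)
    te_embeddings: list[TEEmbedding] = field(default_factory=list)
    transgene_insertion: TransgeneInsertion | None = None
    n_reads: int = 10000
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    p_1U_sense: float = 0.8
    p_1U_antisense: float = 0.8
    pingpong_fraction: float = 0.0
    strand_ratio: float = 0.5
    suppression_zones: list[SuppressionZone] = field(default_factory=list)
    #: references reads are drawn from, weighted by length; defaults to all
    #: cluster-role references (all references when no cluster is declared)
    read_sources: list[str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for p, label in (
            (self.p_1U_sense, "p_1U_sense"),
            (self.p_1U_antisense, "p_1U_antisense"),
            (self.pingpong_fraction, "pingpong_fraction"),
            (self.strand_ratio, "strand_ratio"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {p}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.length_distribution:
            total = sum(self.length_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"length_distribution must sum to 1 (got {total!r})"
                )
            for length in self.length_distribution:
                if not 19 <= length <= 29:
                    raise ValueError(f"read length {length} outside 19..29")
        for zone in self.suppression_zones:
            if not 0.0 <= zone.residual_fraction <= 1.0:
                raise ValueError("suppression residual_fraction must be in [0, 1]")

    # -- config file round-trip ------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        kwargs = dict(raw)
        kwargs["reference_spec"] = [
            ReferenceSpec(**r) for r in kwargs.get("reference_spec", [])
        ]
        kwargs["motif_insertions"] = [
            MotifInsertion(**m) for m in kwargs.get("motif_insertions", [])
        ]
        kwargs["te_embeddings"] = [
            TEEmbedding(**t) for t in kwargs.get("te_embeddings", [])
        ]
        if kwargs.get("transgene_insertion"):
            kwargs["transgene_insertion"] = TransgeneInsertion(
                **kwargs["transgene_insertion"]
            )
        if kwargs.get("length_distribution"):
            kwargs["length_distribution"] = {
                int(k): float(v) for k, v in kwargs["length_distribution"].items()
            }
        kwargs["suppression_zones"] = [
            SuppressionZone(
                interval=GenomicInterval(**z["interval"]),
                residual_fraction=float(z["residual_fraction"]),
            )
            for z in kwargs.get("suppression_zones", [])
        ]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Draw reference sequences and build their annotation set.

    Sequences are uniform 25%-per-base ACGT (a neutral null for both the PWM
    scan and the 1U statistic); motif strings and TE embeddings are then
    substituted verbatim at their stated positions. Returns the sequences and
    a BED-ready interval list: one interval per reference (name = role), one
    per planted motif (name = ``motif:<string>``), one per TE embedding, and
    a 1-bp interval marking the transgene insertion point with its
    orientation in the strand field.
    """
    if not config.reference_spec:
        raise ValueError("reference_spec must be nonempty")
    names = [r.name for r in config.reference_spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate reference names")

    rng = np.random.default_rng(config.seed)
    sequences: dict[str, list[str]] = {}
    annotations: list[GenomicInterval] = []
    lengths: dict[str, int] = {}
    for ref in config.reference_spec:
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=ref.length)
        sequences[ref.name] = list(seq.astype(str))
        lengths[ref.name] = ref.length
        annotations.append(
            GenomicInterval(ref.name, 0, ref.length, ref.role, ".")
        )

    # verbatim substitutions: motifs first, then TE embeddings; overlaps are
    # an error because a silent overwrite would corrupt the truth table
    planted: list[tuple[str, int, int, str]] = []

    def _substitute(refname: str, position: int, payload: str, label: str) -> None:
        if refname not in sequences:
            raise ValueError(f"{label}: unknown reference {refname!r}")
        end = position + len(payload)
        if position < 0 or end > lengths[refname]:
            raise ValueError(
                f"{label}: [{position}, {end}) out of range on {refname} "
                f"(length {lengths[refname]})"
            )
        for other_ref, other_start, other_end, other_label in planted:
            if other_ref == refname and position < other_end and other_start < end:
                raise ValueError(
                    f"overlapping substitutions: {label} at "
                    f"[{position}, {end}) and {other_label} at "
                    f"[{other_start}, {other_end}) on {refname}"
                )
        sequences[refname][position:end] = list(payload)
        planted.append((refname, position, end, label))

    for m in config.motif_insertions:
        _substitute(m.reference, m.position, m.motif.upper(), f"motif {m.motif}")
        annotations.append(
            GenomicInterval(
                m.reference,
                m.position,
                m.position + len(m.motif),
                f"motif:{m.motif.upper()}",
                "+",
            )
        )

    for t in config.te_embeddings:
        if t.te_name not in sequences:
            raise ValueError(f"TE embedding: unknown TE reference {t.te_name!r}")
        payload = "".join(sequences[t.te_name])
        _substitute(t.reference, t.position, payload, f"TE {t.te_name}")
        annotations.append(
            GenomicInterval(
                t.reference,
                t.position,
                t.position + len(payload),
                f"te:{t.te_name}",
                "+",
            )
        )

    tg = config.transgene_insertion
    if tg is not None:
        if tg.reference not in sequences:
            raise ValueError(f"transgene insertion: unknown reference {tg.reference!r}")
        if not 0 <= tg.position < lengths[tg.reference]:
            raise ValueError("transgene insertion position out of range")
        annotations.append(
            GenomicInterval(
                tg.reference,
                tg.position,
                tg.position + 1,
                "transgene_insertion",
                tg.orientation,
            )
        )

    return {name: "".join(chars) for name, chars in sequences.items()}, annotations


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# read simulation

TRUTH_COLUMNS = [
    "read_id",
    "reference",
    "start",
    "end",
    "strand",
    "length",
    "is_pingpong_responder",
    "partner_id",
]


def simulate_reads(
    config: SimulationConfig, references: Mapping[str, str]
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample a read library and its per-read truth table.

    Reads are drawn from the configured source references (length-weighted);
    a fraction ``pingpong_fraction`` is emitted as responder pairs whose 5'
    ends overlap by exactly 10 nt on opposite strands, the rest
    independently with P(plus strand) = ``strand_ratio``.

    The 1U bias is imposed through placement, not mutation: the read's 5'
    base is drawn first (uridine/T with the strand's p_1U, otherwise
    uniform over the non-T bases) and the start position is then sampled
    uniformly among template positions carrying that base. Every read is
    therefore an exact substring (or reverse complement) of its reference
    — it maps back at 0 mismatches — and the realized 1U fraction equals
    p_1U. Reads overlapping a suppression zone are retained with
    probability ``residual_fraction``.

    Returns ``(reads, truth)`` where reads is a list of (id, sequence) and
    truth a DataFrame with one row per surviving read.
    """
    if not references:
        raise ValueError("empty reference set")
    if config.n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if config.n_reads == 0:
        return [], pd.DataFrame(columns=TRUTH_COLUMNS)

    rng = np.random.default_rng(config.seed + 1)  # decoupled from reference draw

    roles = {r.name: r.role for r in config.reference_spec}
    if config.read_sources is not None:
        sources = list(config.read_sources)
    else:
        sources = [n for n in references if roles.get(n) == "cluster"]
        if not sources:
            sources = list(references)
    for s in sources:
        if s not in references:
            raise ValueError(f"read source {s!r} not in reference set")
    src_len = np.array([len(references[s]) for s in sources], dtype=float)
    src_p = src_len / src_len.sum()

    lengths = np.array(sorted(config.length_distribution), dtype=int)
    length_p = np.array([config.length_distribution[l] for l in lengths])

    # per-source lookup tables for placement conditioned on the 5' base:
    # pos_by_base[b] = positions i with ref[i] == b; pair_pos[(b1, b2)] =
    # positions i with ref[i] == b1 and ref[i+9] == b2 (for responder pairs,
    # whose two 5' ends are 9 bp apart on the template)
    pos_by_base: dict[str, dict[str, np.ndarray]] = {}
    pair_pos: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for src in sources:
        arr = np.frombuffer(references[src].encode(), dtype=np.uint8)
        pos_by_base[src] = {
            b: np.nonzero(arr == ord(b))[0] for b in "ACGT"
        }
        pair_pos[src] = {}
        if len(arr) > 9:
            head, tail = arr[:-9], arr[9:]
            for b1 in "ACGT":
                for b2 in "ACGT":
                    pair_pos[src][(b1, b2)] = np.nonzero(
                        (head == ord(b1)) & (tail == ord(b2))
                    )[0]

    def _draw_first_base(p_1u: float) -> str:
        if rng.random() < p_1u:
            return "T"
        return "ACG"[rng.integers(0, 3)]

    def _pick(positions: np.ndarray, lo: int, hi: int) -> int | None:
        """Uniform draw from positions within [lo, hi], or None."""
        i = np.searchsorted(positions, lo, side="left")
        j = np.searchsorted(positions, hi, side="right")
        if i >= j:
            return None
        return int(positions[i + rng.integers(0, j - i)])

    n_pairs = int(round(config.n_reads * config.pingpong_fraction / 2.0))
    n_single = config.n_reads - 2 * n_pairs

    rows: list[tuple] = []
    reads: list[tuple[str, str]] = []
    counter = 0

    def _emit(ref: str, start: int, end: int, strand: str) -> str:
        nonlocal counter
        seq = references[ref][start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        read_id = f"r{counter:07d}"
        counter += 1
        reads.append((read_id, seq))
        rows.append((read_id, ref, start, end, strand, end - start, False, None))
        return read_id

    # independent reads
    for _ in range(n_single):
        ref = sources[rng.choice(len(sources), p=src_p)]
        ref_len = len(references[ref])
        length = int(lengths[rng.choice(len(lengths), p=length_p)])
        if ref_len < length:
            continue
        strand = "+" if rng.random() < config.strand_ratio else "-"
        p_1u = config.p_1U_sense if strand == "+" else config.p_1U_antisense
        first = _draw_first_base(p_1u)
        if strand == "+":
            # 5' end at the start; template base there must equal `first`
            start = _pick(pos_by_base[ref][first], 0, ref_len - length)
            if start is None:
                continue
            _emit(ref, start, start + length, "+")
        else:
            # 5' end at end-1 in plus coordinates; template base there is
            # the complement of the read's first base
            five = _pick(
                pos_by_base[ref][_COMPLEMENT_BASE[first]], length - 1, ref_len - 1
            )
            if five is None:
                continue
            _emit(ref, five + 1 - length, five + 1, "-")

    # responder pairs: minus partner's 5' end sits at (sense 5' + 9)
    for _ in range(n_pairs):
        ref = sources[rng.choice(len(sources), p=src_p)]
        ref_len = len(references[ref])
        if ref_len <= 9:
            continue
        l_plus = int(lengths[rng.choice(len(lengths), p=length_p)])
        l_minus = int(lengths[rng.choice(len(lengths), p=length_p)])
        first_plus = _draw_first_base(config.p_1U_sense)
        first_minus = _draw_first_base(config.p_1U_antisense)
        # plus read [s, s+l_plus) with ref[s] == first_plus; minus read
        # [s+10-l_minus, s+10) with 5' end q = s+9 and ref[q] the
        # complement of first_minus
        lo = max(0, l_minus - 10)
        hi = min(ref_len - l_plus, ref_len - 10)
        if hi < lo:
            continue
        s = _pick(
            pair_pos[ref][(first_plus, _COMPLEMENT_BASE[first_minus])], lo, hi
        )
        if s is None:
            continue
        id_plus = _emit(ref, s, s + l_plus, "+")
        id_minus = _emit(ref, s + 10 - l_minus, s + 10, "-")
        for rid, pid in ((id_plus, id_minus), (id_minus, id_plus)):
            i = int(rid[1:])
            rows[i] = rows[i][:6] + (True, pid)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    # suppression: independent thinning inside each zone
    if config.suppression_zones and len(truth):
        keep = np.ones(len(truth), dtype=bool)
        for i, row in enumerate(truth.itertuples(index=False)):
            for zone in config.suppression_zones:
                if zone.interval.overlaps(row.reference, row.start, row.end):
                    if rng.random() >= zone.residual_fraction:
                        keep[i] = False
                    break
        dropped = set(truth.loc[~keep, "read_id"])
        truth = truth[keep].copy()
        reads = [r for r in reads if r[0] not in dropped]
        # a responder whose partner was suppressed no longer forms a pair
        widowed = truth["partner_id"].isin(dropped)
        truth.loc[widowed, ["is_pingpong_responder", "partner_id"]] = [False, None]
        truth = truth.reset_index(drop=True)

    return reads, truth


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Constant-quality FASTQ; qualities are never used downstream."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_annotations(
    annotations: Sequence[GenomicInterval], outdir: str | Path
) -> dict[str, Path]:
    """One BED file per annotation class (role, motif, te, transgene)."""
    outdir = Path(outdir)
    groups: dict[str, list[GenomicInterval]] = {}
    for iv in annotations:
        key = iv.name.split(":")[0]
        groups.setdefault(key, []).append(iv)
    paths = {}
    for key, ivs in groups.items():
        path = outdir / f"{key}.bed"
        write_bed(ivs, path)
        paths[key] = path
    return paths
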