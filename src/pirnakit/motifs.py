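"""PWM scanning with exact p-value calibration and site-density tests.

A position count matrix (JASPAR plain text, e.g. the Su(Hw) motif
MA0533.1) is converted to a log-odds matrix against a 0-order background
and calibrated exactly: the null distribution of the score of a random
W-mer is computed by position-wise convolution of the epsilon-discretized
score columns, giving P(score >= s) for every attainable score. Scanning
reports every window on either strand whose p-value clears the threshold
(1e-5 by default, the conventional FIMO cutoff for this motif).

The density statistic asks whether motif sites are depleted inside a set
of intervals (piRNA clusters) relative to the whole sequence set: with N
total sites and cluster fraction rho of the genome, the site count inside
clusters is tested against Binomial(N, rho), two-sided and exact; a seeded
permutation null is available as a cross-check.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from scipy import stats

from .intervals import GenomicInterval, merge_intervals, total_length
from .simulate import reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_EPSILON = 1e-3
DEFAULT_P_THRESHOLD = 1e-5


@dataclass
class PWM:
    """Position count matrix with log-odds scores and exact calibration."""

    name: str
    counts: np.ndarray  # shape (4, W), rows in ACGT order
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x W matrix")
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        colsum = self.counts.sum(axis=0)
        freq = (self.counts + self.pseudocount * self.background[:, None]) / (
            colsum + self.pseudocount
        )
        self.log_odds = np.log2(freq / self.background[:, None])
        # integer score grid; all p-value math is exact on this grid
        self.int_scores = np.rint(self.log_odds / self.epsilon).astype(np.int64)
        self._table: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    # -- exact null distribution -----------------------------------------

    def pvalue_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores, tail) with tail[i] = P(score >= scores[i]) under the
        background; scores ascending, tail monotone non-increasing."""
        if self._table is not None:
            return self._table
        lo = int(self.int_scores.min(axis=0).sum())
        hi = int(self.int_scores.max(axis=0).sum())
        probs = np.zeros(hi - lo + 1)
        # convolve one column at a time; offsets keep the array dense
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(self.width):
            col = self.int_scores[:, j]
            new_lo = cur_lo + int(col.min())
            new_hi = cur_lo + len(cur) - 1 + int(col.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                off = cur_lo + int(col[b]) - new_lo
                new[off : off + len(cur)] += cur * self.background[b]
            cur, cur_lo = new, new_lo
        probs[cur_lo - lo : cur_lo - lo + len(cur)] = cur
        support = np.nonzero(probs > 0)[0]
        scores = support + lo
        tail = np.cumsum(probs[support][::-1])[::-1]
        self._table = (scores, tail)
        return self._table

    def pvalue(self, int_score: int) -> float:
        """Exact P(score >= int_score) for a score on the integer grid."""
        scores, tail = self.pvalue_table()
        i = np.searchsorted(scores, int_score, side="left")
        return float(tail[i]) if i < len(scores) else 0.0

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest attainable integer score with p <= p_threshold."""
        scores, tail = self.pvalue_table()
        passing = np.nonzero(tail <= p_threshold)[0]
        if len(passing) == 0:
            return int(scores[-1]) + 1  # unattainable: no window can pass
        return int(scores[passing[0]])


def symmetric_background(sequences: Mapping[str, str] | Sequence[str]) -> np.ndarray:
    """0-order background from the scanned sequences, complement-averaged
    so one null distribution is exact for both strands."""
    seqs = sequences.values() if isinstance(sequences, Mapping) else sequences
    counts = np.zeros(4)
    for seq in seqs:
        for b, i in _BASE_INDEX.items():
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freq = counts / counts.sum()
    at = (freq[0] + freq[3]) / 2
    cg = (freq[1] + freq[2]) / 2
    return np.array([at, cg, cg, at])


def load_jaspar(
    path: str | Path,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    epsilon: float = DEFAULT_EPSILON,
) -> PWM:
    """Load a JASPAR plain-text count matrix (pfm / jaspar formats)."""
    with open(path) as fh:
        text = fh.read()
    fmt = "jaspar" if ("[" in text or ">" in text) else "pfm"
    try:
        motif = bio_motifs.read(io.StringIO(text), fmt)
    except Exception as exc:
        raise ValueError(f"cannot parse JASPAR matrix {path}: {exc}") from exc
    counts = np.array([list(motif.counts[b]) for b in BASES], dtype=float)
    return PWM(
        name=motif.matrix_id or motif.name or Path(path).stem,
        counts=counts,
        background=background if background is not None else np.full(4, 0.25),
        pseudocount=pseudocount,
        epsilon=epsilon,
    )


def write_jaspar(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name} {pwm.name}\n")
        for i, b in enumerate(BASES):
            row = " ".join(f"{c:g}" for c in pwm.counts[i])
            fh.write(f"{b}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# scanning


@dataclass(frozen=True)
class MotifHit:
    reference: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), 4, dtype=np.int64)  # 4 = N / anything else
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def _window_scores(code: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer score of every window; windows containing N score -inf."""
    W = int_matrix.shape[1]
    n_win = len(code) - W + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    padded = np.vstack([int_matrix, np.zeros(W, dtype=np.int64)])  # row 4: N
    scores = np.zeros(n_win, dtype=np.int64)
    has_n = np.zeros(n_win, dtype=bool)
    for j in range(W):
        col = code[j : j + n_win]
        scores += padded[col, j]
        has_n |= col == 4
    scores[has_n] = np.iinfo(np.int64).min
    return scores


def scan(
    sequences: Mapping[str, str] | str,
    pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    reference_name: str = "seq",
) -> list[MotifHit]:
    """Scan both strands of one or more sequences for motif hits.

    Every window whose exact p-value is <= p_threshold is reported; windows
    containing N are skipped. A palindromic site hit on both strands yields
    two records at the same interval (deduplicate with ``unique_sites`` for
    density counting).
    """
    if isinstance(sequences, str):
        sequences = {reference_name: sequences}
    thresh = pwm.score_threshold(p_threshold)
    W = pwm.width
    # minus-strand hits found by scanning the reverse-complement matrix on
    # the forward sequence; the symmetric background makes the same
    # calibration exact for both strands
    rc_matrix = pwm.int_scores[_COMPLEMENT_INDEX, ::-1]
    hits: list[MotifHit] = []
    for name, seq in sequences.items():
        code = _encode(seq.upper())
        for strand, matrix in (("+", pwm.int_scores), ("-", rc_matrix)):
            scores = _window_scores(code, matrix)
            for pos in np.nonzero(scores >= thresh)[0]:
                s = int(scores[pos])
                hits.append(
                    MotifHit(
                        reference=name,
                        start=int(pos),
                        end=int(pos) + W,
                        strand=strand,
                        score=s * pwm.epsilon,
                        pvalue=pwm.pvalue(s),
                    )
                )
    hits.sort(key=lambda h: (h.reference, h.start, h.strand))
    return hits


def unique_sites(hits: Sequence[MotifHit]) -> list[tuple[str, int, int]]:
    """Collapse strand-duplicate hits to one site per interval: 'one site
    per N kb' counts loci, not strand matches."""
    return sorted({(h.reference, h.start, h.end) for h in hits})


# ---------------------------------------------------------------------------
# density depletion test


@dataclass(frozen=True)
class DensityResult:
    n_sites_genome: int
    genome_length: int
    n_sites_clusters: int
    cluster_length: int
    pvalue: float
    test: str
    permutation_pvalue: float | None = None

    @property
    def density_genome(self) -> float:
        """bp per site, genome-wide; inf when no sites."""
        return self.genome_length / self.n_sites_genome if self.n_sites_genome else math.inf

    @property
    def density_clusters(self) -> float:
        return (
            self.cluster_length / self.n_sites_clusters
            if self.n_sites_clusters
            else math.inf
        )


def depletion_test(
    hits: Sequence[MotifHit] | Sequence[tuple[str, int, int]],
    cluster_intervals: Sequence[GenomicInterval],
    genome_length: int,
    n_permutations: int = 0,
    seed: int = 0,
) -> DensityResult:
    """Exact two-sided binomial test of site depletion inside clusters.

    A deduplicated site falls in a cluster when its start position lies
    inside a (merged) cluster interval. Under the uniform null each of the
    N sites lands in clusters with probability rho = L_clusters / L_genome,
    so the cluster count is Binomial(N, rho). The optional permutation null
    rotates all sites by a random offset (circular, per reference pooled to
    genome scale) and reports the fraction of permutations with as few or
    fewer cluster sites.
    """
    if hits and isinstance(hits[0], MotifHit):
        sites = unique_sites(hits)  # type: ignore[arg-type]
    else:
        sites = sorted(set(hits))  # type: ignore[arg-type]
    clusters = merge_intervals(list(cluster_intervals))
    L_clusters = total_length(clusters)
    if L_clusters == 0:
        raise ValueError("cluster set has zero length")
    if L_clusters > genome_length:
        raise ValueError("cluster length exceeds genome length")

    def _in_cluster(ref: str, start: int) -> bool:
        return any(iv.contains_point(ref, start) for iv in clusters)

    N = len(sites)
    x = sum(1 for ref, start, _end in sites if _in_cluster(ref, start))
    rho = L_clusters / genome_length
    if N == 0:
        pvalue = 1.0
    else:
        pvalue = stats.binomtest(x, N, rho, alternative="two-sided").pvalue

    perm_p = None
    if n_permutations > 0 and N > 0:
        rng = np.random.default_rng(seed)
        # circular rotation within each reference preserves site spacing
        by_ref: dict[str, list[int]] = {}
        for ref, start, _end in sites:
            by_ref.setdefault(ref, []).append(start)
        extreme = 0
        for _ in range(n_permutations):
            x_perm = 0
            for ref, starts in by_ref.items():
                shift = int(rng.integers(0, genome_length))
                for s in starts:
                    if _in_cluster(ref, (s + shift) % genome_length):
                        x_perm += 1
            if x_perm <= x:
                extreme += 1
        perm_p = (extreme + 1) / (n_permutations + 1)

    return DensityResult(
        n_sites_genome=N,
        genome_length=genome_length,
        n_sites_clusters=x,
        cluster_length=L_clusters,
        pvalue=float(pvalue),
        test="exact binomial (two-sided)",
        permutation_pvalue=perm_p,
    )
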