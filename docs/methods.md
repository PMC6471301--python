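# Methods

This note records the models, conventions and design choices behind
pirnakit, in the order data flows through the pipeline.

## Synthetic libraries

The generator emulates the statistical structure of an ovarian small-RNA
library from a dual-strand piRNA cluster. References are drawn from a
uniform 25%-per-base background — a neutral null for both the PWM scan and
the 1U statistic — with motif strings, TE-consensus copies and a transgene
insertion point substituted or annotated on top. A transgene insertion is
modelled as an annotated point (BED interval of width 1, orientation in
the strand field) plus a suppression zone, not as a sequence splice: every
downstream statistic consumes host-genome coordinates, and keeping them
stable is worth more than sequence realism at the junction. The transgene
sequence itself, when needed, is a separate reference with role
`transgene`.

Reads are sampled from the configured source references
(length-weighted; by default all cluster-role references). Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `n_reads` | 10,000 | attempted reads per library |
| `length_distribution` | 24–29 peak (70%), 21 nt (10%), see code | read-length spectrum |
| `p_1U_sense/antisense` | 0.8 | probability of a 5′ uridine, per strand |
| `pingpong_fraction` | 0.0 | fraction of reads emitted as 10-nt-overlap pairs |
| `strand_ratio` | 0.5 | P(plus strand) for independent reads |
| suppression `residual_fraction` | — | retention probability inside a zone |

**1U by placement, not mutation.** The read's 5′ base is drawn first (T
with probability p_1U, otherwise uniform over the non-T bases) and the
start position is then sampled uniformly among template positions carrying
that base. This makes the realized 1U fraction exactly p_1U while keeping
every read an exact substring (or reverse complement) of its reference, so
the library maps back at 0 mismatches. Overwriting the base instead would
leave ~75% of reads unmappable at 0 mismatches and silently destroy the
ping-pong and flank statistics.

**Ping-pong pairs.** A responder pair is a plus-strand read with 5′ end
`s` and a minus-strand partner whose 5′ end sits at `s + 9` (plus
coordinates), i.e. exactly a 10-nt 5′ overlap; both lengths are drawn
independently, and both 5′ bases obey their strand's 1U rule (placement is
conditioned jointly on the two template bases 9 bp apart). When a
suppression zone removes one member of a pair, the survivor's responder
flag is cleared and its partner id nulled, keeping the truth table's
mutuality invariant.

**What the generator does not emulate:** sequencing errors, adapters,
quality-score variation, PCR duplicates, non-uniform genomic base
composition, nested TE fragment structure, or transcription-level
correlations along the cluster. Passing tests therefore demonstrate that
the statistics recover planted signals under clean conditions; they do not
certify behaviour under sequencing artefacts, which real libraries should
address upstream (adapter/quality trimming) before entering the pipeline.

## Collapsing and mapping

Reads are collapsed to unique sequences with copy counts; records are
ordered lexicographically so the result is independent of input order.
Length window 19–29 nt (the minimal length filter is >18 nt); reads
containing N are dropped and logged.

The mapper reports every placement on either strand with Hamming distance
≤ the configured bound (0–3). Substitutions only — for 19–29-nt reads on
desk-scale references indel alignment buys nothing, and the two regimes of
interest are exact matching against genomic references and ≤3 mismatches
against TE consensus sequences whose copies have diverged. N never matches
any base (it can still be spanned within the mismatch budget). Exact
matching uses substring search; bounded-mismatch matching uses a
vectorized sliding-window comparison. `n_hits` counts a read's placements
across the entire reference set; "uniquely mapped" means `n_hits == 1`.
Alignments from an external aligner can be imported from SAM (NM tag for
mismatches, NH or per-read record counts for `n_hits`); coordinates are
converted to 0-based half-open at that boundary and everything internal is
0-based half-open, BED-native.

Multi-mapper policy is set per analysis, not globally: `unique` for
locus-specific statistics (the transgene flank), `weighted`
(count/n_hits) for family-level abundance (TE consensus tables), where
dropping multi-mappers would discard most of the signal and
double-counting would inflate it.

## Abundance statistics

The RPM denominator is the library's total mapped 19–29-nt count (each
read counted once, via the count/n_hits identity). Using mapped rather
than sequenced reads makes libraries with different contamination levels
comparable; the choice is configurable at every call site via
`library_total`.

Fold changes between libraries use a pseudo-count of 1 RPM on both sides:
`(RPM_b + 1)/(RPM_a + 1)`. This keeps folds finite for families absent
from one library and shrinks ratios built on a handful of reads toward 1.

Genic piRNA gain calls flag a gene (per strand) when RPM_A < 0.5,
RPM_B ≥ 5 and the pseudo-counted fold ≥ 10. There is no field convention
for "de novo genic piRNA production"; these defaults separate
clearly-silent from clearly-producing loci at typical library depths and
are deliberately configurable rather than tuned.

The flank statistic counts uniquely mapped piRNA-class reads overlapping
the 10-kb window 3′ of the transgene insertion by ≥1 bp, per genomic
strand; "3′" is resolved through the orientation recorded in the
insertion's strand field (a minus-strand transgene looks upstream in
genome coordinates).

## Ping-pong signature

The overlap histogram is accumulated per reference and summed before the
Z-score. Pairs are weighted by the product of collapsed counts
(`unique` mode, weighting each distinct sequence once, is available); the
focal overlap is 10 and the background window K = 20 with the sample
standard deviation (ddof = 1) over the 19 non-focal bins. A flat
background (sd = 0) is reported as degenerate with z = 0 rather than
±inf — it arises on empty or single-pair inputs where no signature claim
is defensible. The Z-score is invariant to read order and to uniform
scaling of the histogram.

## PWM scanning and density testing

Log-odds follow `log2((count + pseudocount·bg) / (colsum + pseudocount) /
bg)` with pseudocount 0.1. Scores are discretized to an integer grid at
ε = 1e-3 bits; the null score distribution is computed by position-wise
convolution over that grid, which is exact for the discretized matrix (the
unit tests verify equality with full 4^W enumeration). Because every
window is scored with the same integer matrix, p-value lookups during
scanning are exact, not interpolated.

The scanning background is the 0-order composition of the scanned
sequences, averaged with its complement so that a single null distribution
is exact for both strands; minus-strand hits are found by scanning the
reverse-complemented matrix over the forward sequence. Windows containing
N are skipped. The default threshold is exact p ≤ 1e-5. Note the
false-positive budget this implies: the expected number of chance hits is
(attainable tail at threshold) × 2 × genome length, which for sharp
matrices sits one order of magnitude below `2 × 1e-5 × L` but is not
zero — relevant when interpreting site densities on large references.

For density counting, strand-duplicate hits at the same interval collapse
to one site ("one site per N kb" counts loci, not strand matches). The
depletion test merges cluster intervals, computes ρ = L_clusters /
L_genome and tests the cluster site count x against Binomial(N, ρ),
two-sided and exact. The test behind the original density comparison is
not identified in the literature the pipeline follows; the exact binomial
is this package's normative choice, and a circular-rotation permutation
null (seeded, spacing-preserving) is provided as a cross-check. Under
uniform site placement the test is calibrated (type-I error 4–5% at
α = 0.05 — slightly conservative, as exact tests on discrete data are)
and detects a threefold cluster-rate deficit at α = 1e-5 with power >0.9
from 500 sites.

## qPCR arithmetic

Amplification efficiency is fixed at 2 (no efficiency correction), so one
cycle is one doubling; the base is configurable. Replicates are aggregated
mean-first: mean Ct per (sample, target) feeds the ΔΔCt point estimate,
while the SEM comes from replicate-level ΔCt values (paired by replicate
id) combined in quadrature across the two samples and mapped to the fold
scale as `fold·ln(2)·SEM(ΔΔCt)`. ChIP percent input is
`input_fraction × 2^(Ct_input − Ct_IP) × 100`; `input_fraction` has no
default — it depends on the experiment's dilution scheme and silently
assuming one would corrupt every downstream number. The genotype
comparison is the classic equal-variance unpaired t-test (Welch by flag),
with the conventional star thresholds (0.05 / 0.01 / 0.001).

## Problem sizes and numerical choices

The bundled analyses and the acceptance script run at desk scale, chosen
so each statistic operates in the regime where its asymptotics hold while
the whole suite stays interactive: 20,000-read libraries over 10–30-kb
references for the ping-pong, 1U and flank statistics; 200 reads × 10 kb
for mapper-oracle comparisons; width ≤ 6 for exhaustive PWM enumeration;
1000 simulations for depletion-test calibration; and a 7-Mb genome with a
900-kb cluster compartment for the site-density regime (one site per
45 kb in clusters, one per 14 kb overall, planted at fixed spacing with
jitter — the regime specifies densities, not a sampling law, and
deterministic planting keeps the planted rate exact while chance hits add
the small background quantified above).

Ties and degenerate inputs: empty inputs yield NaN (1U) or flagged
degenerate results (ping-pong) rather than exceptions; zero-length cluster
sets and zero RPM denominators are errors, since no statistic defined on
them exists. All randomness flows from a single integer seed per run;
fixed seed gives byte-identical outputs.

## Known limitations

The mapper is O(reads × genome) and intended for desk-scale references
(clusters, consensus sets, transgenes); genome-scale mapping should go
through an external aligner and SAM import. The exact p-value table is
exact for the ε-discretized matrix, not the real-valued one; ε = 1e-3
makes the difference irrelevant at any practical threshold but it is a
discretization nonetheless. Ping-pong partner assignment per read, phasing
(3′–5′ distance) signatures, differential-expression modelling and motif
discovery are out of scope.
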