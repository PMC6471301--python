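"""Abundance statistics: classes, 1U bias, RPM, coverage, flanks, folds."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pirnakit.intervals import GenomicInterval
from pirnakit.mapping import AlignmentRecord, align
from pirnakit.reads import CollapsedRead
from pirnakit.stats import (
    LibraryStats,
    classify,
    coverage_profile,
    feature_rpm_table,
    flanking_abundance,
    genic_gain_calls,
    rpm,
    te_family_table,
    u1_bias,
)

from conftest import random_reads, random_sequence


def _aln(read_id="r0", ref="chr", start=100, length=24, strand="+",
         n_hits=1, count=1, mm=0):
    return AlignmentRecord(
        read_id=read_id, reference=ref, start=start, end=start + length,
        strand=strand, mismatches=mm, n_hits=n_hits, count=count,
    )


class TestClassify:
    @pytest.mark.parametrize("length,expected", [
        (24, "piRNA"), (29, "piRNA"), (26, "piRNA"),
        (21, "siRNA"),
        (22, "other"), (19, "other"), (23, "other"),
    ])
    def test_size_windows(self, length, expected):
        assert classify(length) == expected


class TestRpm:
    @pytest.mark.parametrize("count,total,expected", [
        (10, 1e6, 10.0), (0, 12345, 0.0), (7, 3.5e6, 2.0),
    ])
    def test_arithmetic(self, count, total, expected):
        assert rpm(count, total) == pytest.approx(expected)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            rpm(1, 0)


class TestU1Bias:
    def test_all_t_reads_give_one(self):
        reads = {f"r{i}": CollapsedRead(f"r{i}", "T" + "A" * 23, 1) for i in range(3)}
        alns = [_aln(read_id=f"r{i}", start=i * 30) for i in range(3)]
        assert u1_bias(alns, reads) == 1.0

    def test_count_weighting(self):
        reads = {
            "t": CollapsedRead("t", "T" + "A" * 23, 3),
            "a": CollapsedRead("a", "C" + "A" * 23, 1),
        }
        alns = [_aln(read_id="t", count=3), _aln(read_id="a", start=200)]
        assert u1_bias(alns, reads) == pytest.approx(0.75)

    def test_exclusion_zone_removes_reads(self):
        reads = {
            "in": CollapsedRead("in", "T" + "A" * 23, 1),
            "out": CollapsedRead("out", "C" + "A" * 23, 1),
        }
        alns = [_aln(read_id="in", start=100), _aln(read_id="out", start=500)]
        mask = [GenomicInterval("chr", 120, 130)]  # 1-bp overlap with [100,124)
        assert u1_bias(alns, reads, exclude=mask) == 0.0

    def test_empty_after_filters_is_nan(self):
        assert math.isnan(u1_bias([], {}))

    def test_non_pirna_lengths_ignored(self):
        reads = {"si": CollapsedRead("si", "T" + "A" * 20, 1)}
        assert math.isnan(u1_bias([_aln(read_id="si", length=21)], reads))

    def test_recovers_simulated_bias_within_3se(self, cluster_reference):
        """Estimate within 3 binomial SE of the simulated p_1U."""
        from pirnakit.reads import collapse
        from pirnakit.simulate import SimulationConfig, ReferenceSpec, simulate_reads

        p_true = 0.8
        cfg = SimulationConfig(
            seed=42,
            reference_spec=[ReferenceSpec("cl", 10000, "cluster")],
            n_reads=10000,
            p_1U_sense=p_true,
            p_1U_antisense=p_true,
        )
        from pirnakit.simulate import generate_reference

        refs, _ = generate_reference(cfg)
        sim_reads, _ = simulate_reads(cfg, refs)
        collapsed = collapse([s for _, s in sim_reads])
        alns = align(collapsed, refs)
        est = u1_bias(alns, {r.id: r for r in collapsed})
        n = sum(r.count for r in collapsed if 24 <= r.length <= 29)
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(est - p_true) < 3 * se


class TestCoverageProfile:
    def test_single_unique_read_unit_profile(self):
        iv = GenomicInterval("chr", 0, 300)
        profile = coverage_profile([_aln(start=100)], iv, library_total=1e6)
        assert profile[100:124].tolist() == [1.0] * 24
        assert profile.sum() == pytest.approx(24.0)

    def test_multimapper_zero_under_unique_policy(self):
        iv = GenomicInterval("chr", 0, 300)
        profile = coverage_profile(
            [_aln(n_hits=2)], iv, library_total=1e6, policy="unique"
        )
        assert profile.sum() == 0.0

    def test_matches_per_base_oracle(self, rng):
        iv = GenomicInterval("chr", 0, 500)
        alns = [
            _aln(
                read_id=f"r{i}",
                start=int(rng.integers(0, 450)),
                length=int(rng.integers(19, 30)),
                strand="+" if rng.random() < 0.5 else "-",
                count=int(rng.integers(1, 4)),
                n_hits=int(rng.integers(1, 3)),
            )
            for i in range(60)
        ]
        total = 2e6
        profile = coverage_profile(alns, iv, library_total=total, policy="weighted")
        oracle = np.zeros(500)
        for a in alns:
            for pos in range(a.start, min(a.end, 500)):
                oracle[pos] += a.count / a.n_hits * 1e6 / total
        assert np.allclose(profile, oracle)

    def test_profile_integrates_to_weighted_read_bases(self, rng):
        iv = GenomicInterval("chr", 0, 1000)
        alns = [
            _aln(read_id=f"r{i}", start=int(rng.integers(0, 900)),
                 count=int(rng.integers(1, 5)))
            for i in range(40)
        ]
        total = 1e6
        profile = coverage_profile(alns, iv, library_total=total)
        expected = sum(a.count * a.length for a in alns) * 1e6 / total
        assert profile.sum() == pytest.approx(expected)


class TestFlankingAbundance:
    def test_empty_window_is_zero(self):
        insertion = GenomicInterval("chr", 5000, 5001, "transgene_insertion", "+")
        rec = flanking_abundance([], insertion, library_total=1e6)
        assert (rec.sense_rpm, rec.antisense_rpm) == (0.0, 0.0)

    def test_counts_match_hand_tally(self):
        insertion = GenomicInterval("chr", 5000, 5001, "transgene_insertion", "+")
        alns = [
            _aln(read_id="a", start=6000, count=2),                # in window, +
            _aln(read_id="b", start=7000, strand="-", count=3),    # in window, -
            _aln(read_id="c", start=4000),                         # upstream: out
            _aln(read_id="d", start=16000),                        # beyond 10 kb
            _aln(read_id="e", start=6500, n_hits=2, count=10),     # multi: dropped
            _aln(read_id="f", start=8000, length=21),              # siRNA: dropped
        ]
        rec = flanking_abundance(alns, insertion, library_total=1e6)
        assert rec.sense_rpm == pytest.approx(2.0)
        assert rec.antisense_rpm == pytest.approx(3.0)

    def test_minus_orientation_looks_upstream(self):
        insertion = GenomicInterval("chr", 15000, 15001, "transgene_insertion", "-")
        alns = [_aln(read_id="a", start=6000), _aln(read_id="b", start=16000)]
        rec = flanking_abundance(alns, insertion, library_total=1e6)
        # 3' of a minus-strand transgene = [5000, 15000): only read a counts
        assert rec.sense_rpm == pytest.approx(1.0)
        assert "5000-15000" in rec.feature


class TestTeFamilyTable:
    def test_identical_libraries_fold_one(self):
        alns = [_aln(ref="TE1", read_id="a"), _aln(ref="TE2", read_id="b", count=5)]
        table = te_family_table(alns, alns, 1e6, 1e6)
        assert np.allclose(table["fold_change"], 1.0)

    def test_pseudocount_formula(self):
        a = []  # family absent: 0 RPM
        b = [_aln(ref="TE1", read_id="x", count=200)]
        table = te_family_table(a, b, 1e6, 1e6, pseudo_rpm=1.0)
        row = table.set_index("feature").loc["TE1"]
        assert row["fold_change"] == pytest.approx(201.0 / 1.0)

    def test_multimapper_weight_sharing(self):
        # one read hitting two families contributes half to each
        alns = [
            _aln(ref="TE1", read_id="m", n_hits=2, count=4),
            _aln(ref="TE2", read_id="m", n_hits=2, count=4),
        ]
        table = feature_rpm_table(alns, 1e6)
        assert table.set_index("feature")["total_rpm"].tolist() == [2.0, 2.0]


class TestGenicGainCalls:
    def test_gain_flagged(self):
        t = pd.DataFrame({"gene": ["g"], "strand": ["+"], "rpm_a": [0.0], "rpm_b": [50.0]})
        assert genic_gain_calls(t)["flagged"].tolist() == [True]

    def test_expressed_baseline_not_flagged(self):
        t = pd.DataFrame({"gene": ["g"], "strand": ["+"], "rpm_a": [40.0], "rpm_b": [50.0]})
        assert genic_gain_calls(t)["flagged"].tolist() == [False]

    def test_matches_brute_force_filter(self, rng):
        n = 200
        t = pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "strand": rng.choice(["+", "-"], size=n),
            "rpm_a": rng.exponential(2.0, size=n),
            "rpm_b": rng.exponential(20.0, size=n),
        })
        got = genic_gain_calls(t, t_low=0.5, t_high=5.0, t_fold=10.0, pseudo_rpm=1.0)
        expected = [
            (row.rpm_a < 0.5)
            and (row.rpm_b >= 5.0)
            and ((row.rpm_b + 1) / (row.rpm_a + 1) >= 10.0)
            for row in t.itertuples()
        ]
        assert got["flagged"].tolist() == expected


class TestLibraryStats:
    def test_table_sums_to_total_mapped(self, rng):
        ref = {"chr": random_sequence(rng, 3000)}
        reads = random_reads(rng, 50) + [
            CollapsedRead("planted", ref["chr"][100:126], 4)
        ]
        alns = align(reads, ref, max_mismatch=0)
        lib = LibraryStats.from_alignments(alns)
        assert lib.length_strand_table.values.sum() == pytest.approx(lib.total_mapped)
        # every mapped read counted exactly once
        mapped_ids = {a.read_id for a in alns}
        expected = sum(r.count for r in reads if r.id in mapped_ids)
        assert lib.total_mapped == pytest.approx(expected)
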