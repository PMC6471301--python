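"""Synthetic-data generator: determinism, substitution contracts, truth table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pirnakit.intervals import GenomicInterval
from pirnakit.simulate import (
    MotifInsertion,
    ReferenceSpec,
    SimulationConfig,
    SuppressionZone,
    TEEmbedding,
    TransgeneInsertion,
    generate_reference,
    reverse_complement,
    simulate_reads,
    write_fasta,
    write_fastq,
)


def _config(**kwargs) -> SimulationConfig:
    base = dict(
        seed=7,
        reference_spec=[ReferenceSpec("cl", 10000, "cluster")],
        n_reads=1000,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestGenerateReference:
    def test_seed_determinism_byte_identical(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            cfg = _config()
            refs, ann = generate_reference(cfg)
            fasta = tmp_path / f"{run}.fasta"
            write_fasta(refs, fasta)
            paths.append(fasta.read_bytes())
        assert paths[0] == paths[1]

    def test_lengths_match_spec(self):
        cfg = _config(
            reference_spec=[
                ReferenceSpec("a", 5000, "cluster"),
                ReferenceSpec("b", 20000, "neutral"),
            ]
        )
        refs, _ = generate_reference(cfg)
        assert len(refs["a"]) == 5000
        assert len(refs["b"]) == 20000

    def test_motif_substituted_verbatim(self):
        motif = "TGCATACTTCT"
        cfg = _config(motif_insertions=[MotifInsertion("cl", 100, motif)])
        refs, ann = generate_reference(cfg)
        assert refs["cl"][100 : 100 + len(motif)] == motif
        names = {iv.name for iv in ann}
        assert f"motif:{motif}" in names

    def test_te_embedding_creates_repeat(self):
        cfg = _config(
            reference_spec=[
                ReferenceSpec("cl", 10000, "cluster"),
                ReferenceSpec("te1", 500, "TE_consensus"),
            ],
            te_embeddings=[TEEmbedding("te1", "cl", 2000)],
        )
        refs, _ = generate_reference(cfg)
        assert refs["cl"][2000:2500] == refs["te1"]

    def test_overlapping_substitutions_error_names_both(self):
        cfg = _config(
            motif_insertions=[
                MotifInsertion("cl", 100, "TGCATACTTCT"),
                MotifInsertion("cl", 105, "AAAAAA"),
            ]
        )
        with pytest.raises(ValueError, match="overlapping"):
            generate_reference(cfg)

    def test_position_out_of_range_errors(self):
        cfg = _config(motif_insertions=[MotifInsertion("cl", 9995, "TGCATACTTCT")])
        with pytest.raises(ValueError, match="out of range"):
            generate_reference(cfg)

    def test_background_roughly_uniform(self):
        refs, _ = generate_reference(_config())
        seq = refs["cl"]
        freqs = np.array([seq.count(b) for b in "ACGT"]) / len(seq)
        assert np.allclose(freqs, 0.25, atol=0.03)

    def test_transgene_annotation_point(self):
        cfg = _config(transgene_insertion=TransgeneInsertion("cl", 4000, "-"))
        _, ann = generate_reference(cfg)
        tg = [iv for iv in ann if iv.name == "transgene_insertion"]
        assert len(tg) == 1
        assert (tg[0].start, tg[0].strand) == (4000, "-")


class TestSimulateReads:
    def test_zero_reads(self):
        cfg = _config(n_reads=0)
        refs, _ = generate_reference(cfg)
        reads, truth = simulate_reads(cfg, refs)
        assert reads == [] and len(truth) == 0

    def test_negative_reads_rejected(self):
        with pytest.raises(ValueError):
            _config(n_reads=-1)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads(_config(), {})

    def test_seed_determinism_byte_identical_fastq(self, tmp_path):
        blobs = []
        for run in ("a", "b"):
            cfg = _config()
            refs, _ = generate_reference(cfg)
            reads, _ = simulate_reads(cfg, refs)
            path = tmp_path / f"{run}.fastq"
            write_fastq(reads, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]

    def test_truth_consistency_reads_match_template(self, cluster_reference, cluster_library):
        """Every read is reproduced by extracting its truth interval."""
        references, _ = cluster_reference
        reads, truth = cluster_library
        seq_by_id = dict(reads)
        for row in truth.itertuples(index=False):
            template = references[row.reference][row.start : row.end]
            if row.strand == "-":
                template = reverse_complement(template)
            assert seq_by_id[row.read_id] == template

    def test_one_truth_row_per_read(self, cluster_library):
        reads, truth = cluster_library
        assert sorted(truth["read_id"]) == sorted(r for r, _ in reads)
        assert truth["read_id"].is_unique

    def test_responder_fraction_within_binomial_ci(self):
        """Responder fraction lands in the 99% binomial CI around the target."""
        cfg = _config(n_reads=20000, pingpong_fraction=0.3, seed=11)
        refs, _ = generate_reference(cfg)
        _, truth = simulate_reads(cfg, refs)
        frac = truth["is_pingpong_responder"].mean()
        lo, hi = sps.binom.ppf([0.005, 0.995], 20000, 0.3) / 20000
        assert lo <= frac <= hi

    def test_responder_partners_mutual_with_10nt_overlap(self):
        cfg = _config(n_reads=2000, pingpong_fraction=0.4, seed=5)
        refs, _ = generate_reference(cfg)
        _, truth = simulate_reads(cfg, refs)
        t = truth.set_index("read_id")
        responders = t[t["is_pingpong_responder"]]
        assert len(responders) > 0
        for rid, row in responders.iterrows():
            partner = t.loc[row["partner_id"]]
            assert partner["partner_id"] == rid
            plus, minus = (row, partner) if row["strand"] == "+" else (partner, row)
            assert plus["strand"] == "+" and minus["strand"] == "-"
            # minus 5' end (end-1) sits 9 bp downstream of the plus 5' end
            assert minus["end"] - 1 - plus["start"] == 9

    def test_length_distribution_recovered(self):
        cfg = _config(n_reads=20000, seed=3)
        refs, _ = generate_reference(cfg)
        _, truth = simulate_reads(cfg, refs)
        observed = truth["length"].value_counts(normalize=True)
        for length, p in cfg.length_distribution.items():
            assert observed.get(length, 0.0) == pytest.approx(p, abs=0.02)

    def test_strand_ratio_respected(self):
        cfg = _config(n_reads=10000, strand_ratio=0.7, seed=9)
        refs, _ = generate_reference(cfg)
        _, truth = simulate_reads(cfg, refs)
        assert truth["strand"].eq("+").mean() == pytest.approx(0.7, abs=0.03)

    def test_suppression_zone_thins_reads(self):
        zone = SuppressionZone(GenomicInterval("cl", 2000, 4000), 0.1)
        cfg_full = _config(n_reads=20000, seed=13)
        refs, _ = generate_reference(cfg_full)
        _, truth_full = simulate_reads(cfg_full, refs)
        cfg_sup = _config(n_reads=20000, seed=13, suppression_zones=[zone])
        _, truth_sup = simulate_reads(cfg_sup, refs)

        def in_zone(t: pd.DataFrame) -> int:
            return ((t["start"] < 4000) & (t["end"] > 2000)).sum()

        assert in_zone(truth_sup) < 0.25 * in_zone(truth_full)
        # outside the zone the library is untouched in expectation
        assert len(truth_sup) > 0.7 * len(truth_full)

    def test_widowed_responders_unflagged(self):
        zone = SuppressionZone(GenomicInterval("cl", 0, 10000), 0.5)
        cfg = _config(n_reads=4000, pingpong_fraction=0.5, seed=21, suppression_zones=[zone])
        refs, _ = generate_reference(cfg)
        _, truth = simulate_reads(cfg, refs)
        responders = truth[truth["is_pingpong_responder"]]
        surviving = set(truth["read_id"])
        assert all(pid in surviving for pid in responders["partner_id"])
        widowed = truth[~truth["is_pingpong_responder"]]
        assert widowed["partner_id"].isna().all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("p_1U_sense", 1.5),
            ("pingpong_fraction", -0.1),
            ("strand_ratio", 2.0),
        ],
    )
    def test_probability_bounds(self, field, value):
        with pytest.raises(ValueError):
            _config(**{field: value})

    def test_length_distribution_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _config(length_distribution={24: 0.5, 25: 0.6})

    def test_yaml_round_trip(self, tmp_path):
        cfg = _config(
            motif_insertions=[MotifInsertion("cl", 100, "TGCATACTTCT")],
            transgene_insertion=TransgeneInsertion("cl", 4000, "-"),
            suppression_zones=[
                SuppressionZone(GenomicInterval("cl", 2000, 4000), 0.1)
            ],
        )
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        loaded = SimulationConfig.from_yaml(path)
        assert loaded == cfg
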