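"""Generator calibration, determinism, and generator/reader agreement."""

import filecmp
import math

import numpy as np
import pytest

from l1context import GeneratorConfig, simulate, write_simulation
from l1context.io_formats import (
    read_fragments,
    read_locus_catalog,
    read_loops,
    read_methylation,
    read_peaks,
    read_read_pairs,
)
from l1context.simulate import generate_catalog, generate_fragments


class TestCatalog:
    def test_default_class_counts_within_two_sigma(self, default_sim):
        cfg = default_sim.config
        counts = default_sim.truth["true_class"].value_counts()
        for cls, p in zip(
            ("expressed", "transitional", "passive", "closed"), cfg.class_probs
        ):
            sigma = math.sqrt(cfg.n_loci * p * (1 - p))
            assert abs(counts.get(cls, 0) - cfg.n_loci * p) <= 2 * sigma

    def test_zero_loci(self):
        cfg = GeneratorConfig(n_loci=0, chrom_length=100_000)
        loci, truth, genome, consensus = generate_catalog(cfg)
        assert loci == [] and len(truth) == 0

    def test_overcrowded_chromosome_rejected(self):
        with pytest.raises(ValueError, match="longer chromosome"):
            generate_catalog(GeneratorConfig(n_loci=100, chrom_length=1_000_000))

    def test_loci_non_overlapping_and_full_length(self, default_sim):
        loci = default_sim.loci
        for prev, cur in zip(loci, loci[1:]):
            assert prev.end <= cur.start
        assert all(l.length >= 5500 for l in loci)

    def test_l1hs_promoters_carry_motifs(self, small_sim):
        """L1Hs bodies diverge only ~0.5% from the consensus, so promoter
        motif scanning finds near-consensus YY1 sites."""
        from l1context import scan_promoter_motifs

        seqs = small_sim.promoter_sequences()
        l1hs_ids = set(
            small_sim.truth[small_sim.truth["subfamily"] == "L1Hs"]["locus_id"]
        )
        res = scan_promoter_motifs({k: v for k, v in seqs.items() if k in l1hs_ids})
        yy1 = res[res["motif"] == "YY1"]
        assert (yy1["mismatches"] <= 2).mean() >= 0.8


class TestFragments:
    def test_expressed_counts_match_configured_mean(self):
        cfg = GeneratorConfig(
            n_loci=300,
            chrom_length=5_000_000,
            p_expressed=0.8,
            p_transitional=0.05,
            p_passive=0.05,
            n_background_fragments=0,
            seed=2,
        )
        loci, truth, *_ = generate_catalog(cfg)
        generate_fragments(cfg, truth, loci)
        expr = truth[truth["true_class"] == "expressed"]
        assert len(expr) >= 200
        assert abs(expr["true_count"].mean() - 71.2) <= 7.12

    def test_passive_fragments_originate_upstream(self, default_sim):
        sim = default_sim
        by_id = {l.locus_id: l for l in sim.loci}
        passive = sim.truth[sim.truth["true_class"] == "passive"]
        assert len(passive) >= 1
        for lid in passive["locus_id"]:
            loc = by_id[lid]
            frags = [
                f
                for f in sim.fragments
                if f.concordant
                and f.strand == loc.strand
                and f.frag_start < loc.end
                and f.frag_end > loc.start
            ]
            upstream = [
                f
                for f in frags
                if (loc.strand == "+" and f.five_prime() < loc.start)
                or (loc.strand == "-" and f.five_prime() >= loc.end)
            ]
            assert len(upstream) / len(frags) >= 0.9

    def test_closed_and_transitional_emit_no_fragments(self, default_sim):
        silent = default_sim.truth[
            default_sim.truth["true_class"].isin(["closed", "transitional"])
        ]
        assert (silent["true_count"] == 0).all()


class TestPeaksAndMethylation:
    def test_transitional_all_atac_positive(self, default_sim):
        tr = default_sim.truth[default_sim.truth["true_class"] == "transitional"]
        assert tr["true_atac"].all()

    def test_expressed_methylation_mean_near_configured(self):
        cfg = GeneratorConfig(
            n_loci=300,
            chrom_length=5_000_000,
            p_expressed=0.8,
            seed=4,
        )
        sim = simulate(cfg)
        expr = sim.truth[sim.truth["true_class"] == "expressed"]
        assert len(expr) >= 100
        assert abs(expr["true_meth_percent"].dropna().mean() - 36.26) <= 5.0

    def test_expressed_mark_count_mean_near_configured(self):
        cfg = GeneratorConfig(
            n_loci=300,
            chrom_length=5_000_000,
            p_expressed=0.8,
            seed=6,
        )
        sim = simulate(cfg)
        expr = sim.truth[sim.truth["true_class"] == "expressed"]
        assert abs(expr["true_mark_count"].mean() - 5.91) <= 0.5


class TestLoops:
    def test_expressed_polII_rate_near_configured(self):
        cfg = GeneratorConfig(
            n_loci=300,
            chrom_length=5_000_000,
            p_expressed=0.8,
            seed=8,
        )
        sim = simulate(cfg)
        expr = sim.truth[sim.truth["true_class"] == "expressed"]
        assert len(expr) >= 100
        rate = expr["true_polII"].mean()
        sigma = math.sqrt(0.9 * 0.1 / len(expr))
        assert abs(rate - 0.9) <= 3 * sigma + 0.01

    def test_loops_canonically_ordered(self, default_sim):
        for loop in default_sim.loops:
            assert loop.anchor1[1] <= loop.anchor2[1]


class TestDeterminismAndRoundTrip:
    def test_byte_identical_outputs_under_fixed_seed(self, small_sim, tmp_path):
        cfg = small_sim.config
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_simulation(simulate(cfg), d1)
        p2 = write_simulation(simulate(cfg), d2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seeds_differ(self, tmp_path):
        c1 = GeneratorConfig(n_loci=10, chrom_length=500_000, seed=1)
        c2 = GeneratorConfig(n_loci=10, chrom_length=500_000, seed=2)
        s1, s2 = simulate(c1), simulate(c2)
        assert s1.genome != s2.genome

    def test_written_files_reproduce_objects(self, small_sim, tmp_path):
        """No generator/reader drift: files re-read through the format
        layer reproduce the in-memory objects."""
        paths = write_simulation(small_sim, tmp_path / "sim")
        assert read_locus_catalog(paths["catalog"]) == small_sim.loci
        assert read_methylation(paths["methylation"]) == small_sim.meth_records
        assert read_loops(paths["loops"]) == small_sim.loops
        assert read_read_pairs(paths["wgs_pairs"]) == small_sim.wgs_pairs
        atac = read_peaks(paths["atac"], "ATAC")
        assert atac.intervals == small_sim.atac_track.intervals
        frags = read_fragments(paths["fragments"])
        orig = small_sim.fragments
        assert [
            (f.chrom, f.frag_start, f.frag_end, f.strand, f.concordant)
            for f in frags
            if f.concordant
        ] == [
            (f.chrom, f.frag_start, f.frag_end, f.strand, f.concordant)
            for f in orig
            if f.concordant
        ]
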