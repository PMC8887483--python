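"""Naive unique aligner and mate-anchoring L1Hs detection."""

import numpy as np
import pytest

from l1context import (
    GeneratorConfig,
    L1Locus,
    Parameters,
    align_read,
    anchor_filter,
    detect_l1hs,
    revcomp,
    simulate,
)
from l1context.l1hs import Alignment, align_reads_to_genome


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignRead:
    def test_exact_unique_substring(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 2000)
        read = ref[500:600]
        aln = align_read(read, ref, max_mm=3)
        assert aln is not None
        assert (aln.start, aln.mismatches, aln.orientation) == (500, 0, "forward")

    def test_reverse_orientation_detected(self):
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 2000)
        aln = align_read(revcomp(ref[700:800]), ref, max_mm=3)
        assert aln is not None and aln.orientation == "reverse" and aln.start == 700

    def test_duplicated_placement_fails_uniqueness(self):
        rng = np.random.default_rng(2)
        unit = random_seq(rng, 300)
        ref = unit + random_seq(rng, 200) + unit
        read = unit[100:200]
        assert align_read(read, ref, max_mm=3, require_unique=True) is None
        aln = align_read(read, ref, max_mm=3, require_unique=False)
        assert aln is not None and not aln.unique

    def test_mismatch_cap(self):
        rng = np.random.default_rng(3)
        ref = random_seq(rng, 500)
        read = list(ref[100:200])
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in range(0, 52, 2):  # 26 substitutions
            read[i] = flip[read[i]]
        assert align_read("".join(read), ref, max_mm=25) is None

    def test_read_longer_than_reference(self):
        assert align_read("ACGT" * 100, "ACGTACGT", max_mm=3) is None


class TestAnchorFilter:
    @pytest.mark.parametrize(
        "start,orientation,expected",
        [
            (100, "reverse", True),
            (100, "forward", False),
            (699, "reverse", True),
            (700, "reverse", False),
        ],
    )
    def test_first_700bp_reverse_only(self, start, orientation, expected):
        aln = Alignment("r", "consensus", start, start + 100, orientation, 0, True)
        assert anchor_filter(aln, 700) is expected


class TestGenomeAligner:
    def test_matches_exhaustive_scan(self):
        """Seeded multi-read placement agrees with the naive per-read scan."""
        rng = np.random.default_rng(42)
        genome = {"c1": random_seq(rng, 30_000), "c2": random_seq(rng, 20_000)}
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        reads = {}
        expected = {}
        for i in range(30):
            chrom = "c1" if i % 2 else "c2"
            pos = int(rng.integers(0, len(genome[chrom]) - 100))
            seq = list(genome[chrom][pos : pos + 100])
            for j in rng.choice(100, size=int(rng.integers(0, 4)), replace=False):
                seq[j] = flip[seq[j]]
            read = "".join(seq)
            if i % 3 == 0:
                read = revcomp(read)
            reads[f"r{i}"] = read
            expected[f"r{i}"] = (chrom, pos)
        placed = align_reads_to_genome(reads, genome, max_mm=3)
        for rid, (chrom, pos) in expected.items():
            # cross-check against the exhaustive single-reference scan
            naive = align_read(reads[rid], genome[chrom], max_mm=3, chrom=chrom)
            if naive is None:
                assert rid not in placed or placed[rid].chrom != chrom
            else:
                assert rid in placed
                assert (placed[rid].chrom, placed[rid].start) == (chrom, naive.start)

    def test_random_read_unplaced(self):
        rng = np.random.default_rng(9)
        genome = {"c1": random_seq(rng, 10_000)}
        assert align_reads_to_genome({"r": random_seq(rng, 100)}, genome, 3) == {}


class TestDetection:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        consensus = random_seq(rng, 6000)
        chrom = random_seq(rng, 20_000)
        # plant the element at 10_000 on the plus strand
        chrom = chrom[:10_000] + consensus + chrom[10_000 + 6000 :]
        locus = L1Locus("L1-hs1", "chrT", 10_000, 16_000, "+", "L1Hs")
        return consensus, {"chrT": chrom}, locus

    def test_planted_junction_pair_detected(self):
        consensus, genome, locus = self._setup()
        mate_a = revcomp(consensus[50:150])
        mate_b = genome["chrT"][9_600 : 9_700]  # 300 bp upstream of the 5' end
        results = detect_l1hs([("p0", mate_a, mate_b)], consensus, genome, [locus])
        assert [r.locus_id for r in results] == ["L1-hs1"]
        assert results[0].supporting_pairs == 1

    def test_anchor_outside_700bp_not_detected(self):
        consensus, genome, locus = self._setup()
        mate_a = revcomp(consensus[1000:1100])
        mate_b = genome["chrT"][9_600 : 9_700]
        assert detect_l1hs([("p0", mate_a, mate_b)], consensus, genome, [locus]) == []

    def test_zero_pairs(self):
        consensus, genome, locus = self._setup()
        assert detect_l1hs([], consensus, genome, [locus]) == []

    def test_non_l1hs_loci_never_reported(self):
        consensus, genome, locus = self._setup()
        older = L1Locus("L1-old", "chrT", 10_000, 16_000, "+", "L1PA2")
        mate_a = revcomp(consensus[50:150])
        mate_b = genome["chrT"][9_600 : 9_700]
        assert detect_l1hs([("p0", mate_a, mate_b)], consensus, genome, [older]) == []

    def test_order_invariance(self, small_sim):
        sim = small_sim
        fwd = detect_l1hs(sim.wgs_pairs, sim.consensus, sim.genome, sim.loci)
        rev = detect_l1hs(sim.wgs_pairs[::-1], sim.consensus, sim.genome, sim.loci)
        assert [(r.locus_id, r.supporting_pairs) for r in fwd] == [
            (r.locus_id, r.supporting_pairs) for r in rev
        ]

    def test_noiseless_recall_is_perfect(self):
        cfg = GeneratorConfig(
            n_loci=30,
            chrom_length=1_200_000,
            n_l1hs_present=5,
            n_l1hs_absent=5,
            pairs_per_junction=3,
            n_decoy_pairs=10,
            base_error_rate=0.0,
            seed=11,
        )
        sim = simulate(cfg)
        results = detect_l1hs(sim.wgs_pairs, sim.consensus, sim.genome, sim.loci)
        detected = {r.locus_id for r in results}
        present = set(sim.truth[sim.truth["l1hs_present"]]["locus_id"])
        absent = (
            set(sim.truth[sim.truth["subfamily"] == "L1Hs"]["locus_id"]) - present
        )
        assert detected >= present  # recall 1.0
        assert not (detected & absent)  # absent loci never detected
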