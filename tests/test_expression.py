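"""Fragment counting, normalization, curation and expression classes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1context import (
    FragmentRecord,
    L1Locus,
    Parameters,
    classify_expression,
    count_fragments,
    curate_locus,
    downsample_fragments,
    normalize_counts,
)
from l1context.expression import (
    CLASS_EXPRESSED,
    CLASS_MODEST,
    CLASS_PASSIVE,
    CLASS_UNEXPRESSED,
    CURATION_FAIL,
    CURATION_NOT_EVALUATED,
    CURATION_PASS,
    round_half_away,
)


def locus(lid="A", start=10_000, end=16_000, strand="+"):
    return L1Locus(lid, "chr1", start, end, strand, "L1PA2")


def frag(start, end, strand="+", concordant=True, chrom="chr1"):
    return FragmentRecord(chrom, start, end, strand, concordant, "f")


class TestCountFragments:
    def test_counts_concordant_sense_overlaps_only(self):
        loc = locus()
        frags = [
            frag(11_000, 11_300),
            frag(12_000, 12_300),
            frag(15_900, 16_200),  # 100 bp overlap still counts
            frag(13_000, 13_300, concordant=False),
            frag(13_000, 13_300, strand="-"),  # antisense
            frag(20_000, 20_300),  # outside
        ]
        assert count_fragments(frags, [loc]) == {"A": 3}

    def test_tie_broken_by_largest_overlap(self):
        a = locus("A", 0, 6000)
        b = locus("B", 6000, 12_000)
        # 200 bp in A, 50 bp in B
        assert count_fragments([frag(5800, 6050)], [a, b]) == {"A": 1, "B": 0}

    def test_equal_overlap_goes_to_leftmost(self):
        a = locus("A", 0, 6000)
        b = locus("B", 6000, 12_000)
        assert count_fragments([frag(5900, 6100)], [a, b]) == {"A": 1, "B": 0}

    def test_single_assignment_conservation(self, default_sim):
        counts = count_fragments(default_sim.fragments, default_sim.loci)
        n_concordant = sum(1 for f in default_sim.fragments if f.concordant)
        assert sum(counts.values()) <= n_concordant


class TestNormalization:
    @pytest.mark.parametrize(
        "sample,expected",
        [(16_581_681, 1.83), (7_419_177, 4.09)],
    )
    def test_depth_factors_at_two_decimals(self, sample, expected):
        _, factor, _ = normalize_counts({}, sample, 30_324_454)
        assert factor == expected

    def test_identity_factor(self):
        normalized, factor, _ = normalize_counts({"A": 7}, 1000, 1000)
        assert factor == 1.0 and normalized == {"A": 7}

    def test_rounding_half_away(self):
        normalized, _, _ = normalize_counts({"A": 10}, 16_581_681, 30_324_454)
        assert normalized == {"A": 18}  # 18.3 -> 18

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts({}, 0, 10)

    def test_rpm(self):
        _, _, rpm = normalize_counts({"A": 5}, 1_000_000, 1_000_000)
        assert rpm == {"A": 5.0}

    @pytest.mark.parametrize("x,expected", [(18.3, 18), (18.5, 19), (-2.5, -3), (0.0, 0)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected


class TestCuration:
    def test_promoter_origin_passes(self):
        loc = locus()
        frags = [frag(10_000 + 40 * i, 10_400 + 40 * i) for i in range(20)]
        assert curate_locus(loc, frags) == CURATION_PASS

    def test_upstream_readthrough_fails(self):
        loc = locus()
        # all fragments begin 3 kb upstream and read through the promoter
        frags = [frag(7_000, 11_000 + 10 * i) for i in range(20)]
        assert curate_locus(loc, frags) == CURATION_FAIL

    def test_no_fragments_not_evaluated(self):
        assert curate_locus(locus(), []) == CURATION_NOT_EVALUATED

    def test_minus_strand_promoter_origin_passes(self):
        loc = locus(strand="-")
        frags = [frag(15_200 + 10 * i, 15_700 + 10 * i, strand="-") for i in range(20)]
        assert curate_locus(loc, frags) == CURATION_PASS

    def test_synthetic_passive_loci_rejected(self, default_sim, default_table):
        truth = default_sim.truth
        merged = default_table.merge(truth[["locus_id", "true_class"]], on="locus_id")
        passive = merged[merged["true_class"] == "passive"]
        assert len(passive) >= 1
        rejected = (passive["curation"] == CURATION_FAIL).mean()
        assert rejected >= 0.9


class TestClassification:
    @pytest.mark.parametrize(
        "count,curation,threshold,expected",
        [
            (26, CURATION_PASS, 20, CLASS_EXPRESSED),
            (0, CURATION_NOT_EVALUATED, 20, CLASS_UNEXPRESSED),
            (5, CURATION_PASS, 20, CLASS_MODEST),
            (5, CURATION_PASS, 5, CLASS_EXPRESSED),  # stimulation mode
            (25, CURATION_FAIL, 20, CLASS_PASSIVE),
        ],
    )
    def test_rules(self, count, curation, threshold, expected):
        assert classify_expression(count, curation, threshold) == expected

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_for_curated_loci(self, low, delta):
        a = classify_expression(low, CURATION_PASS if low else CURATION_NOT_EVALUATED, 20)
        b = classify_expression(
            low + delta, CURATION_PASS if low + delta else CURATION_NOT_EVALUATED, 20
        )
        rank = {CLASS_UNEXPRESSED: 0, CLASS_MODEST: 1, CLASS_EXPRESSED: 2}
        assert rank[b] >= rank[a]


class TestDownsampling:
    def _frags(self, n):
        return [frag(100 * i, 100 * i + 50) for i in range(n)]

    def test_identity_and_empty(self):
        frags = self._frags(10)
        assert downsample_fragments(frags, 10, seed=3) == frags
        assert downsample_fragments(frags, 0, seed=3) == []

    def test_over_target_rejected(self):
        with pytest.raises(ValueError):
            downsample_fragments(self._frags(5), 6, seed=0)

    def test_seed_determinism(self):
        frags = self._frags(1000)
        a = downsample_fragments(frags, 500, seed=11)
        b = downsample_fragments(frags, 500, seed=11)
        c = downsample_fragments(frags, 500, seed=12)
        assert a == b
        assert a != c

    def test_downsampling_preserves_expressed_calls(self, default_sim, default_table):
        """Downsampling a deep library to a shallower total keeps >=95% of
        expressed calls at the matched (low-depth) threshold."""
        from l1context import call_expression

        sim = default_sim
        expressed_before = set(
            default_table[default_table["expression_class"] == CLASS_EXPRESSED]["locus_id"]
        )
        # depth ratio of the shallower to the deeper reference library
        target = int(len(sim.fragments) * 16_581_681 / 30_324_454)
        sub = downsample_fragments(sim.fragments, target, seed=5)
        params = Parameters()
        expr = call_expression(sim.loci, sub, threshold=params.low_depth_threshold)
        expressed_after = {
            e.locus_id for e in expr if e.expression_class == CLASS_EXPRESSED
        }
        kept = len(expressed_before & expressed_after) / len(expressed_before)
        assert kept >= 0.95
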