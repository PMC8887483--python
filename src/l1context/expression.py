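"""Per-locus expression calling from stranded paired-end fragments.

A fragment counts toward a locus when it is concordant, overlaps the
locus body by at least 1 bp, and its transcription strand matches the
element strand. Each fragment is assigned to at most one locus (largest
overlap wins, then the leftmost locus), so summed locus counts never
exceed the number of concordant fragments.

Manual curation of read origin (inspecting alignments to confirm that
reads start at the L1 promoter rather than reading through from an
upstream one) is automated by two criteria: a minimum fraction of
counted fragments must begin within the promoter region of the element,
and per-bp coverage in the 1 kb upstream flank must not rival coverage
over the promoter itself.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .models import FragmentRecord, L1Locus, Parameters, intervals_overlap

CURATION_PASS = "pass"
CURATION_FAIL = "fail_upstream_origin"
CURATION_NOT_EVALUATED = "not_evaluated"

CLASS_EXPRESSED = "expressed"
CLASS_PASSIVE = "passive_transcription"
CLASS_MODEST = "potential_modest"
CLASS_UNEXPRESSED = "unexpressed"


@dataclass
class LocusExpression:
    locus_id: str
    raw_count: int
    normalized_count: int
    rpm: float
    curation: str
    expression_class: str


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def count_fragments(
    fragments: Iterable[FragmentRecord], catalog: Sequence[L1Locus]
) -> dict[str, int]:
    """Per-locus raw fragment counts with single assignment.

    Ties (equal overlap with several loci) go to the locus with the
    smallest start coordinate.
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for idx, loc in enumerate(catalog):
        trees[(loc.chrom, loc.strand)].addi(loc.start, loc.end, idx)
    counts = {loc.locus_id: 0 for loc in catalog}
    for frag in fragments:
        if not frag.concordant:
            continue
        tree = trees.get((frag.chrom, frag.strand))
        if tree is None:
            continue
        hits = tree.overlap(frag.frag_start, frag.frag_end)
        if not hits:
            continue
        best = max(
            hits,
            key=lambda iv: (
                min(frag.frag_end, iv.end) - max(frag.frag_start, iv.begin),
                -iv.begin,
            ),
        )
        counts[catalog[best.data].locus_id] += 1
    return counts


def normalize_counts(
    raw_counts: dict[str, int],
    sample_total_mapped: int,
    reference_total_mapped: int,
) -> tuple[dict[str, int], float, dict[str, float]]:
    """Depth-normalize counts toward a reference library.

    The scale factor (reference/sample) is reported at 2 decimals and
    applied as such; normalized counts are rounded half-away-from-zero.
    Also returns reads-per-million on the sample's own depth.
    """
    if sample_total_mapped <= 0 or reference_total_mapped <= 0:
        raise ValueError("library totals must be > 0")
    factor = round_half_away(100 * reference_total_mapped / sample_total_mapped) / 100
    normalized = {k: round_half_away(v * factor) for k, v in raw_counts.items()}
    rpm = {k: v * 1e6 / sample_total_mapped for k, v in raw_counts.items()}
    return normalized, factor, rpm


def _coverage_mean(
    fragments: Iterable[FragmentRecord], start: int, end: int
) -> float:
    """Mean per-bp fragment coverage over [start, end)."""
    if end <= start:
        return 0.0
    cov = np.zeros(end - start, dtype=np.int32)
    for fr in fragments:
        lo, hi = max(fr.frag_start, start), min(fr.frag_end, end)
        if lo < hi:
            cov[lo - start : hi - start] += 1
    return float(cov.mean())


def curate_locus(
    locus: L1Locus,
    fragments: Iterable[FragmentRecord],
    params: Parameters | None = None,
) -> str:
    """Automated surrogate for visual curation of read origin.

    ``fragments`` may be any superset of the locus's fragments (e.g. all
    fragments on its chromosome); only concordant, strand-matching ones
    are considered. Passes when (a) at least ``curation_start_fraction``
    of counted fragments have their 5' end within the first
    ``curation_promoter_start_bp`` of the element and (b) upstream-flank
    coverage does not exceed ``curation_upstream_ratio`` times promoter
    coverage. Returns ``not_evaluated`` when no fragment is counted.
    """
    params = params or Parameters()
    relevant = [
        fr
        for fr in fragments
        if fr.concordant and fr.chrom == locus.chrom and fr.strand == locus.strand
    ]
    counted = [
        fr
        for fr in relevant
        if intervals_overlap(fr.frag_start, fr.frag_end, locus.start, locus.end)
    ]
    if not counted:
        return CURATION_NOT_EVALUATED

    first_bp = params.curation_promoter_start_bp
    if locus.strand == "+":
        prom = (locus.start, min(locus.end, locus.start + first_bp))
        flank = (max(0, locus.start - params.curation_upstream_flank), locus.start)
    else:
        prom = (max(locus.start, locus.end - first_bp), locus.end)
        flank = (locus.end, locus.end + params.curation_upstream_flank)

    in_prom = sum(1 for fr in counted if prom[0] <= fr.five_prime() < prom[1])
    start_fraction = in_prom / len(counted)

    prom_cov = _coverage_mean(relevant, *prom)
    flank_cov = _coverage_mean(relevant, *flank)
    if prom_cov > 0:
        ratio = flank_cov / prom_cov
    else:
        ratio = float("inf") if flank_cov > 0 else 0.0

    ok = (
        start_fraction >= params.curation_start_fraction
        and ratio <= params.curation_upstream_ratio
    )
    return CURATION_PASS if ok else CURATION_FAIL


def classify_expression(
    normalized_count: int, curation: str, threshold: int = 20
) -> str:
    """Expression class from the normalized count and curation verdict."""
    if normalized_count < 0:
        raise ValueError("count must be >= 0")
    if normalized_count == 0:
        return CLASS_UNEXPRESSED
    if normalized_count < threshold:
        return CLASS_MODEST
    return CLASS_EXPRESSED if curation == CURATION_PASS else CLASS_PASSIVE


def downsample_fragments(
    fragments: Sequence[FragmentRecord], target_total: int, seed: int
) -> list[FragmentRecord]:
    """Uniform random subset without replacement, input order preserved."""
    n = len(fragments)
    if target_total > n:
        raise ValueError(f"target_total {target_total} exceeds total {n}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=target_total, replace=False))
    return [fragments[i] for i in keep]


def call_expression(
    catalog: Sequence[L1Locus],
    fragments: Sequence[FragmentRecord],
    sample_total_mapped: Optional[int] = None,
    reference_total_mapped: Optional[int] = None,
    threshold: int = 20,
    params: Parameters | None = None,
) -> list[LocusExpression]:
    """Full expression-calling stage: count, normalize, curate, classify.

    With no library totals the scale factor is 1 (the sample is its own
    reference, as for the most deeply sequenced line).
    """
    params = params or Parameters()
    raw = count_fragments(fragments, catalog)
    total = sample_total_mapped or sum(1 for f in fragments if f.concordant) or 1
    ref = reference_total_mapped or total
    normalized, _factor, rpm = normalize_counts(raw, total, ref)

    by_chrom: dict[tuple[str, str], list[FragmentRecord]] = defaultdict(list)
    for fr in fragments:
        if fr.concordant:
            by_chrom[(fr.chrom, fr.strand)].append(fr)

    results: list[LocusExpression] = []
    for loc in catalog:
        if raw[loc.locus_id] == 0:
            curation = CURATION_NOT_EVALUATED
        else:
            curation = curate_locus(loc, by_chrom[(loc.chrom, loc.strand)], params)
        cls = classify_expression(normalized[loc.locus_id], curation, threshold)
        results.append(
            LocusExpression(
                locus_id=loc.locus_id,
                raw_count=raw[loc.locus_id],
                normalized_count=normalized[loc.locus_id],
                rpm=rpm[loc.locus_id],
                curation=curation,
                expression_class=cls,
            )
        )
    return results
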