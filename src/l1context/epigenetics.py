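"""Promoter-window epigenetic annotation of L1 loci.

ATAC association uses a symmetric 500 bp window around the strand-aware
promoter anchor; histone marks use an asymmetric window (500 bp upstream,
300 bp downstream, strand-aware); CpG methylation is summarised over the
first 500 bp of the 5'UTR, i.e. the window extending from the anchor into
the element body. All overlaps are edge-to-edge on half-open intervals
(>= 1 bp shared).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    L1Locus,
    MethylationRecord,
    Parameters,
    PeakTrack,
    intervals_overlap,
    promoter_anchor,
    strand_window,
)


@dataclass
class LocusEpigenetics:
    locus_id: str
    atac: bool
    atac_score: float
    mark_count: int
    mark_flags: dict[str, bool] = field(default_factory=dict)
    meth_percent: Optional[float] = None
    covered_cpgs: int = 0
    total_cpgs: int = 0
    within_gene: bool = False


def _track_hits(
    track: PeakTrack, chrom: str, win_start: int, win_end: int
) -> list[int]:
    """Indices of track intervals intersecting the window."""
    return [
        i
        for i, (c, s, e) in enumerate(track.intervals)
        if c == chrom and intervals_overlap(s, e, win_start, win_end)
    ]


def atac_overlap(
    locus: L1Locus, atac_track: PeakTrack, window: int = 500
) -> tuple[bool, float]:
    """ATAC-positive iff any peak intersects [anchor-window, anchor+window).

    Also returns the best score among overlapping peaks (0 when none, or
    when the track carries no scores) for downstream ranking.
    """
    anchor = promoter_anchor(locus)
    lo, hi = max(0, anchor.position - window), anchor.position + window
    hits = _track_hits(atac_track, anchor.chrom, lo, hi)
    if not hits:
        return False, 0.0
    if atac_track.scores is None:
        return True, 0.0
    return True, max(atac_track.scores[i] for i in hits)


def histone_mark_count(
    locus: L1Locus,
    tracks: Sequence[PeakTrack],
    upstream: int = 500,
    downstream: int = 300,
) -> tuple[int, dict[str, bool]]:
    """Number of tracks with a peak in the strand-aware promoter window.

    Each track (one mark x replicate) contributes at most 1, so the count
    ranges over 0..len(tracks) (12 for a six-mark duplicate panel).
    """
    anchor = promoter_anchor(locus)
    lo, hi = strand_window(anchor, upstream, downstream)
    flags = {
        t.track_name: bool(_track_hits(t, anchor.chrom, lo, hi)) for t in tracks
    }
    return sum(flags.values()), flags


def methylation_percent(
    locus: L1Locus,
    meth_records: Iterable[MethylationRecord],
    window: int = 500,
    weighted: bool = False,
) -> tuple[Optional[float], int, int]:
    """Percent methylated CpGs in the first ``window`` bp of the 5'UTR.

    A covered CpG is called methylated when its methylated fraction is
    >= 0.5; ``meth_percent`` is 100 x methylated / covered. Uncovered
    CpGs count toward ``total_cpgs`` only — they are never treated as
    unmethylated — and a locus with no covered CpG gets ``None`` (it is
    excluded from group summaries). ``weighted=True`` instead averages
    the per-CpG methylated fractions.
    """
    anchor = promoter_anchor(locus)
    if locus.strand == "+":
        lo, hi = anchor.position, anchor.position + window
    else:
        lo, hi = max(0, anchor.position - window), anchor.position
    total = 0
    fractions: list[float] = []
    for rec in meth_records:
        if rec.chrom != locus.chrom or not (lo <= rec.cpg_position < hi):
            continue
        total += 1
        if rec.coverage >= 1:
            fractions.append(rec.methylated_count / rec.coverage)
    covered = len(fractions)
    if covered == 0:
        return None, 0, total
    if weighted:
        pct = 100.0 * float(np.mean(fractions))
    else:
        pct = 100.0 * sum(f >= 0.5 for f in fractions) / covered
    return pct, covered, total


def gene_overlap(
    locus: L1Locus, gene_intervals: Iterable[tuple[str, int, int]]
) -> bool:
    """Strand-agnostic >=1 bp intersection of the locus body with any gene."""
    return any(
        c == locus.chrom and intervals_overlap(s, e, locus.start, locus.end)
        for c, s, e in gene_intervals
    )


def annotate_epigenetics(
    catalog: Sequence[L1Locus],
    atac_track: Optional[PeakTrack] = None,
    histone_tracks: Sequence[PeakTrack] = (),
    meth_records: Iterable[MethylationRecord] = (),
    gene_intervals: Iterable[tuple[str, int, int]] = (),
    params: Parameters | None = None,
    weighted_methylation: bool = False,
) -> list[LocusEpigenetics]:
    params = params or Parameters()
    genes = list(gene_intervals)
    meth_by_chrom: dict[str, list[MethylationRecord]] = {}
    for rec in meth_records:
        meth_by_chrom.setdefault(rec.chrom, []).append(rec)
    out: list[LocusEpigenetics] = []
    for loc in catalog:
        atac, score = (
            atac_overlap(loc, atac_track, params.atac_window)
            if atac_track is not None
            else (False, 0.0)
        )
        count, flags = histone_mark_count(
            loc, histone_tracks, params.histone_upstream, params.histone_downstream
        )
        pct, covered, total = methylation_percent(
            loc,
            meth_by_chrom.get(loc.chrom, ()),
            params.meth_window,
            weighted=weighted_methylation,
        )
        out.append(
            LocusEpigenetics(
                locus_id=loc.locus_id,
                atac=atac,
                atac_score=score,
                mark_count=count,
                mark_flags=flags,
                meth_percent=pct,
                covered_cpgs=covered,
                total_cpgs=total,
                within_gene=gene_overlap(loc, genes),
            )
        )
    return out


def build_feature_table(
    catalog: Sequence[L1Locus],
    expression: Sequence,
    epigenetics: Optional[Sequence[LocusEpigenetics]] = None,
) -> pd.DataFrame:
    """One row per catalog locus, joined on locus_id.

    Missing epigenetic or expression inputs yield explicit NA values,
    never silent zeros. Duplicate locus ids are an error.
    """
    ids = [loc.locus_id for loc in catalog]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate locus_id in catalog: {dupes}")

    base = pd.DataFrame(
        {
            "locus_id": ids,
            "chrom": [l.chrom for l in catalog],
            "start": [l.start for l in catalog],
            "end": [l.end for l in catalog],
            "strand": [l.strand for l in catalog],
            "subfamily": [l.subfamily for l in catalog],
            "intact_orf2": [l.intact_orf2 for l in catalog],
        }
    )

    expr_ids = [e.locus_id for e in expression]
    if len(set(expr_ids)) != len(expr_ids):
        raise ValueError("duplicate locus_id in expression results")
    expr = pd.DataFrame(
        {
            "locus_id": expr_ids,
            "raw_count": [e.raw_count for e in expression],
            "normalized_count": [e.normalized_count for e in expression],
            "rpm": [e.rpm for e in expression],
            "curation": [e.curation for e in expression],
            "expression_class": [e.expression_class for e in expression],
        }
    )
    table = base.merge(expr, on="locus_id", how="left")

    if epigenetics is not None:
        epi = pd.DataFrame(
            {
                "locus_id": [e.locus_id for e in epigenetics],
                "atac": [e.atac for e in epigenetics],
                "atac_score": [e.atac_score for e in epigenetics],
                "mark_count": [e.mark_count for e in epigenetics],
                "meth_percent": [e.meth_percent for e in epigenetics],
                "covered_cpgs": [e.covered_cpgs for e in epigenetics],
                "total_cpgs": [e.total_cpgs for e in epigenetics],
                "within_gene": [e.within_gene for e in epigenetics],
            }
        )
        if epi["locus_id"].duplicated().any():
            raise ValueError("duplicate locus_id in epigenetic results")
        table = table.merge(epi, on="locus_id", how="left")

    for col in ("raw_count", "normalized_count", "mark_count", "covered_cpgs", "total_cpgs"):
        if col in table:
            table[col] = table[col].astype("Int64")
    for col in ("atac", "within_gene"):
        if col in table:
            table[col] = table[col].astype("boolean")
    return table
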