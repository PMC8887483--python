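"""Long-distance regulatory context of L1 promoters.

CTCF loops bound candidate topological domains: a promoter is "within"
a CTCF loop when it lies between the two anchors and both anchors are
within a 500 kb search radius. Pol II loops connect a promoter to a
putative enhancer: a loop is associated when its nearer anchor overlaps
a 500 bp window around the promoter anchor, and the distal anchor is
taken as the enhancer interval. Promoter motif status (YY1, RUNX3) is
scored by a sliding-window Hamming scan against the consensus motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .l1hs import revcomp
from .models import (
    Loop,
    Parameters,
    PeakTrack,
    PromoterAnchor,
    intervals_overlap,
)

MOTIF_CONSENSUS = "consensus"
MOTIF_MUTATED = "mutated"
MOTIF_DELETED = "deleted"


@dataclass
class LocusLoopContext:
    locus_id: str
    in_ctcf_loop: bool
    polII_associated: bool
    enhancer_interval: Optional[tuple[str, int, int]]
    marks_on_l1: int
    marks_on_enhancer: int  # 0 when there is no enhancer

    def __post_init__(self) -> None:
        if self.enhancer_interval is None and self.marks_on_enhancer != 0:
            raise ValueError("marks_on_enhancer must be 0 without an enhancer")


@dataclass(frozen=True)
class MotifResult:
    motif_name: str
    best_position: int
    mismatches: int
    status: str


def _interval_distance(pos: int, start: int, end: int) -> int:
    """Distance from a point to a half-open interval (0 if inside)."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - end + 1
    return 0


def in_ctcf_loop(
    anchor: PromoterAnchor, ctcf_loops: Iterable[Loop], search: int = 500_000
) -> bool:
    """True iff the promoter lies between the anchors of a CTCF loop whose
    anchors are both within ``search`` bp of the promoter position."""
    pos = anchor.position
    for loop in ctcf_loops:
        if loop.loop_type != "CTCF" or loop.anchor1[0] != anchor.chrom:
            continue
        if not (loop.anchor1[1] <= pos <= loop.anchor2[2]):
            continue
        if (
            _interval_distance(pos, loop.anchor1[1], loop.anchor1[2]) <= search
            and _interval_distance(pos, loop.anchor2[1], loop.anchor2[2]) <= search
        ):
            return True
    return False


def polII_association(
    anchor: PromoterAnchor, polII_loops: Iterable[Loop], window: int = 500
) -> Optional[tuple[Loop, tuple[str, int, int]]]:
    """Pol II loop whose nearer anchor overlaps the promoter window.

    Returns (loop, enhancer_interval) where the enhancer is the loop's
    other anchor; with both anchors in the window the more distal one is
    the enhancer. Among several qualifying loops the highest score wins,
    then the smallest span.
    """
    lo, hi = max(0, anchor.position - window), anchor.position + window
    pos = anchor.position
    candidates: list[tuple[float, int, Loop, tuple[str, int, int]]] = []
    for loop in polII_loops:
        if loop.loop_type != "POLII" or loop.anchor1[0] != anchor.chrom:
            continue
        hit1 = intervals_overlap(loop.anchor1[1], loop.anchor1[2], lo, hi)
        hit2 = intervals_overlap(loop.anchor2[1], loop.anchor2[2], lo, hi)
        if not (hit1 or hit2):
            continue
        if hit1 and hit2:
            d1 = _interval_distance(pos, loop.anchor1[1], loop.anchor1[2])
            d2 = _interval_distance(pos, loop.anchor2[1], loop.anchor2[2])
            enhancer = loop.anchor2 if d2 >= d1 else loop.anchor1
        else:
            enhancer = loop.anchor2 if hit1 else loop.anchor1
        span = loop.anchor2[2] - loop.anchor1[1]
        score = loop.score if loop.score is not None else 0.0
        candidates.append((-score, span, loop, enhancer))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1]))
    _, _, loop, enhancer = candidates[0]
    return loop, enhancer


def enhancer_marks(
    enhancer_interval: tuple[str, int, int], tracks: Sequence[PeakTrack]
) -> int:
    """Tracks with >=1 peak intersecting the enhancer interval (no padding)."""
    chrom, start, end = enhancer_interval
    return sum(
        any(
            c == chrom and intervals_overlap(s, e, start, end)
            for c, s, e in t.intervals
        )
        for t in tracks
    )


def motif_scan(
    promoter_seq: str,
    motif: str,
    motif_name: str = "",
    deletion_threshold: int = 6,
) -> MotifResult:
    """Best (minimum-Hamming, leftmost tie) placement of a motif in a
    promoter sequence; more than ``deletion_threshold`` mismatches at the
    best placement is called a deletion of the site."""
    m, n = len(motif), len(promoter_seq)
    if n < m:
        return MotifResult(motif_name, 0, m, MOTIF_DELETED)
    seq = promoter_seq.upper()
    best_pos, best_mm = 0, m + 1
    for i in range(n - m + 1):
        mm = sum(1 for a, b in zip(seq[i : i + m], motif) if a != b)
        if mm < best_mm:
            best_pos, best_mm = i, mm
            if mm == 0:
                break
    if best_mm == 0:
        status = MOTIF_CONSENSUS
    elif best_mm > deletion_threshold:
        status = MOTIF_DELETED
    else:
        status = MOTIF_MUTATED
    return MotifResult(motif_name, best_pos, best_mm, status)


def scan_promoter_motifs(
    promoter_seqs: dict[str, str], params: Parameters | None = None
) -> pd.DataFrame:
    """YY1 and RUNX3 status for each promoter sequence (keyed by locus_id)."""
    params = params or Parameters()
    rows = []
    for locus_id in sorted(promoter_seqs):
        seq = promoter_seqs[locus_id]
        for name, motif in (("YY1", params.yy1_motif), ("RUNX3", params.runx3_motif)):
            res = motif_scan(seq, motif, name, params.motif_deletion_threshold)
            rows.append(
                {
                    "locus_id": locus_id,
                    "motif": name,
                    "best_position": res.best_position,
                    "mismatches": res.mismatches,
                    "status": res.status,
                }
            )
    return pd.DataFrame(rows)


def annotate_loops(
    catalog,
    loops: Sequence[Loop],
    histone_tracks: Sequence[PeakTrack],
    mark_counts: Optional[dict[str, int]] = None,
    params: Parameters | None = None,
) -> list[LocusLoopContext]:
    """Per-locus loop/enhancer context.

    ``mark_counts`` (locus_id -> promoter mark count) is reused when the
    promoter panel was already computed; otherwise marks_on_l1 is counted
    over the locus body.
    """
    from .models import promoter_anchor

    params = params or Parameters()
    ctcf = [l for l in loops if l.loop_type == "CTCF"]
    polII = [l for l in loops if l.loop_type == "POLII"]
    out = []
    for locus in catalog:
        anchor = promoter_anchor(locus)
        assoc = polII_association(anchor, polII, params.polII_window)
        if assoc is None:
            enhancer, enh_marks = None, 0
        else:
            enhancer = assoc[1]
            enh_marks = enhancer_marks(enhancer, histone_tracks)
        if mark_counts is not None:
            on_l1 = mark_counts.get(locus.locus_id, 0)
        else:
            on_l1 = enhancer_marks((locus.chrom, locus.start, locus.end), histone_tracks)
        out.append(
            LocusLoopContext(
                locus_id=locus.locus_id,
                in_ctcf_loop=in_ctcf_loop(anchor, ctcf, params.ctcf_search),
                polII_associated=assoc is not None,
                enhancer_interval=enhancer,
                marks_on_l1=on_l1,
                marks_on_enhancer=enh_marks,
            )
        )
    return out


def _tally(flags: Sequence[bool]) -> str:
    yes = sum(bool(f) for f in flags)
    label = "Yes" if 2 * yes >= len(flags) else "No"
    return f"{label} ({yes}/{len(flags)})"


def summarize_loop_table(groups: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-group long-distance interaction summary.

    ``groups`` maps a group name (e.g. expressed / transitional /
    unexpressed) to a per-locus frame with columns locus_id, reads,
    atac, ctcf_loop, polII_loop, marks_on_l1, marks_on_enhancer. Emits
    the per-locus rows plus one AVERAGE row per group carrying the mean
    and sample (n-1) standard deviation of reads and mark counts, and
    Yes/No tallies for the boolean columns.
    """
    from .stats import group_summary

    rows = []
    for group, df in groups.items():
        if len(df) == 0:
            raise ValueError(f"group {group!r} is empty")
        for _, r in df.iterrows():
            rows.append(
                {
                    "group": group,
                    "locus_id": r["locus_id"],
                    "reads": r["reads"],
                    "atac": _yesno(r["atac"]),
                    "ctcf_loop": _yesno(r["ctcf_loop"]),
                    "polII_loop": _yesno(r["polII_loop"]),
                    "marks_on_l1": r["marks_on_l1"],
                    "marks_on_enhancer": r["marks_on_enhancer"],
                }
            )
        reads_mean, reads_sd, _ = group_summary(df["reads"].tolist())
        l1_mean, l1_sd, _ = group_summary(df["marks_on_l1"].tolist())
        enh_mean, enh_sd, _ = group_summary(df["marks_on_enhancer"].tolist())
        rows.append(
            {
                "group": group,
                "locus_id": "AVERAGE",
                "reads": round(reads_mean, 1),
                "atac": _tally(df["atac"].tolist()),
                "ctcf_loop": _tally(df["ctcf_loop"].tolist()),
                "polII_loop": _tally(df["polII_loop"].tolist()),
                "marks_on_l1": f"{_fmt(l1_mean)} (STDEV: {_fmt(l1_sd)})",
                "marks_on_enhancer": f"{_fmt(enh_mean)} (STDEV: {_fmt(enh_sd)})",
            }
        )
    return pd.DataFrame(rows)


def _yesno(x) -> str:
    return "Yes" if bool(x) else "No"


def _fmt(x: float) -> str:
    """One decimal, trailing .0 stripped (report style)."""
    s = f"{x:.1f}"
    return s[:-2] if s.endswith(".0") else s


def select_top_loci(
    table: pd.DataFrame, n: int = 10, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Top-n loci per headline category for the interaction summary:
    expressed ranked by normalized reads, transitional by ATAC peak
    score, unexpressed (closed) drawn uniformly at random (seeded)."""
    need = {"epigenetic_class", "normalized_count", "atac_score"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    expressed = (
        table[table["epigenetic_class"] == "expressed"]
        .sort_values("normalized_count", ascending=False, kind="stable")
        .head(n)
    )
    transitional = (
        table[table["epigenetic_class"] == "transitional"]
        .sort_values("atac_score", ascending=False, kind="stable")
        .head(n)
    )
    closed = table[table["epigenetic_class"] == "unexpressed_closed"]
    rng = np.random.default_rng(seed)
    take = min(n, len(closed))
    idx = rng.choice(len(closed), size=take, replace=False) if take else []
    unexpressed = closed.iloc[sorted(idx)]
    return {"expressed": expressed, "transitional": transitional, "unexpressed": unexpressed}
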