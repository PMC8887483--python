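"""Mate-anchoring detection of L1Hs loci from whole-genome read pairs.

The youngest L1 subfamily (L1Hs) is nearly sequence-identical across
copies, so unique mapping of reads inside the element fails. Detection
instead anchors one mate of a pair inside the repeat and places the
other mate uniquely in flanking genomic sequence:

1. each mate is aligned to the L1 consensus (ungapped, unique best,
   <= ``max_mm_consensus`` mismatches); mates landing in the first
   ``consensus_anchor`` bp in reverse orientation point out of the 5'
   end of an element;
2. the partner mate of each anchoring read is aligned uniquely to the
   genome (<= ``max_mm_genome`` mismatches);
3. partner alignments intersecting the strand-aware upstream window of
   an annotated L1Hs locus count as support for that locus.

Alignment is an exhaustive-equivalent ungapped Hamming scan of both
strands. On large references the scan is accelerated with a pigeonhole
seed filter (disjoint k-mers with k = read_length // (max_mm + 1)),
which provably enumerates every position within the mismatch cap, so
results match the naive scan exactly. This aligner targets synthetic,
desk-scale references (up to a few tens of Mb), not production genomes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .models import L1Locus, Parameters

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode_read(seq: str) -> np.ndarray:
    """Bytes of the read; ambiguous bases mapped to a value that can never
    match a reference byte (so N counts as a mismatch even against N)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[bad] = 0
    return arr


def _encode_ref(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[bad] = 255
    return arr


@dataclass(frozen=True)
class Alignment:
    """Ungapped alignment of a read to one reference sequence."""

    read_id: str
    chrom: str
    start: int  # 0-based on the reference forward strand
    end: int
    orientation: str  # "forward" or "reverse"
    mismatches: int
    unique: bool


@dataclass
class DetectionResult:
    locus_id: str
    supporting_pairs: int
    mate_positions: list[tuple[str, int, int]] = field(default_factory=list)


def _scan_distances(read_arr: np.ndarray, ref_arr: np.ndarray) -> np.ndarray:
    """Hamming distance of the read at every reference offset."""
    m = len(read_arr)
    if len(ref_arr) < m:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(ref_arr, m)
    return (windows != read_arr).sum(axis=1)


def align_read(
    read: str,
    reference: str,
    max_mm: int,
    require_unique: bool = True,
    chrom: str = "ref",
    read_id: str = "",
) -> Optional[Alignment]:
    """Exhaustive ungapped scan of both strands of one reference.

    Returns the minimum-Hamming placement iff its distance is within
    ``max_mm`` and (when uniqueness is required) strictly better than
    every other placement on either strand; otherwise ``None``.
    """
    if len(read) > len(reference):
        return None
    ref_arr = _encode_ref(reference)
    d_fwd = _scan_distances(_encode_read(read), ref_arr)
    d_rev = _scan_distances(_encode_read(revcomp(read)), ref_arr)
    dists = np.concatenate([d_fwd, d_rev])
    if dists.size == 0:
        return None
    flat = int(np.argmin(dists))
    best_d = int(dists[flat])
    if best_d > max_mm:
        return None
    if dists.size > 1:
        second_d = int(np.partition(dists, 1)[1])
    else:
        second_d = best_d + 1
    unique = second_d > best_d
    if require_unique and not unique:
        return None
    orientation = "forward" if flat < d_fwd.size else "reverse"
    pos = flat if flat < d_fwd.size else flat - d_fwd.size
    return Alignment(
        read_id=read_id,
        chrom=chrom,
        start=pos,
        end=pos + len(read),
        orientation=orientation,
        mismatches=best_d,
        unique=unique,
    )


def anchor_filter(aln: Alignment, anchor_bp: int = 700) -> bool:
    """True for consensus alignments starting in the first ``anchor_bp``
    bases and oriented in reverse relative to the consensus plus strand."""
    return aln.start < anchor_bp and aln.orientation == "reverse"


# ---------------------------------------------------------------------------
# Seeded multi-read genome alignment (exhaustive-equivalent)
# ---------------------------------------------------------------------------

def _rolling_hashes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 hash of every k-mer; windows containing ambiguous bases get
    a sentinel that matches nothing."""
    code = np.full(arr.shape, 4, dtype=np.uint64)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        h = h * np.uint64(5) + code[j : j + n]
        ok &= code[j : j + n] != 4
    h[~ok] = np.uint64(2**63)
    return h


def align_reads_to_genome(
    reads: Mapping[str, str],
    genome: Mapping[str, str],
    max_mm: int,
    require_unique: bool = True,
) -> dict[str, Alignment]:
    """Unique-best ungapped placement of many reads on a multi-sequence
    reference, equivalent to the exhaustive scan.

    A placement with <= ``max_mm`` mismatches must contain an exact copy
    of at least one of ``max_mm + 1`` disjoint read k-mers (pigeonhole),
    so scanning the genome k-mer hashes against all read seeds finds the
    complete candidate set; candidates are then verified by Hamming
    distance and the strict-uniqueness rule applied.
    """
    if not reads:
        return {}
    min_len = min(len(s) for s in reads.values())
    k = min(27, max(1, min_len // (max_mm + 1)))

    # seed hash -> list of (read_id, orientation, offset in oriented read)
    seed_map: dict[int, list[tuple[str, str, int]]] = defaultdict(list)
    oriented: dict[tuple[str, str], np.ndarray] = {}
    for rid, seq in reads.items():
        for orientation, s in (("forward", seq), ("reverse", revcomp(seq))):
            arr = _encode_read(s)
            oriented[(rid, orientation)] = arr
            n_seeds = max_mm + 1
            for j in range(n_seeds):
                off = j * k
                if off + k > len(s):
                    break
                h = _rolling_hashes(_encode_read(s[off : off + k]), k)
                if h.size:
                    seed_map[int(h[0])].append((rid, orientation, off))
    seed_hashes = np.array(sorted(seed_map), dtype=np.uint64)

    # candidate placements per read: (chrom, orientation, start) -> checked
    cand: dict[str, set[tuple[str, str, int]]] = defaultdict(set)
    encoded_ref: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        ref_arr = _encode_ref(seq)
        encoded_ref[chrom] = ref_arr
        gh = _rolling_hashes(ref_arr, k)
        if gh.size == 0:
            continue
        hit_idx = np.nonzero(np.isin(gh, seed_hashes))[0]
        for pos in hit_idx:
            for rid, orientation, off in seed_map[int(gh[pos])]:
                start = int(pos) - off
                if 0 <= start <= len(seq) - len(reads[rid]):
                    cand[rid].add((chrom, orientation, start))

    results: dict[str, Alignment] = {}
    for rid, placements in cand.items():
        scored: list[tuple[int, str, str, int]] = []
        for chrom, orientation, start in placements:
            arr = oriented[(rid, orientation)]
            ref_arr = encoded_ref[chrom]
            d = int((ref_arr[start : start + len(arr)] != arr).sum())
            if d <= max_mm:
                scored.append((d, chrom, orientation, start))
        if not scored:
            continue
        scored.sort()
        best = scored[0]
        unique = len(scored) == 1 or scored[1][0] > best[0]
        if require_unique and not unique:
            continue
        results[rid] = Alignment(
            read_id=rid,
            chrom=best[1],
            start=best[3],
            end=best[3] + len(reads[rid]),
            orientation=best[2],
            mismatches=best[0],
            unique=unique,
        )
    return results


# ---------------------------------------------------------------------------
# Detection pipeline
# ---------------------------------------------------------------------------

def upstream_window(locus: L1Locus, window: int) -> tuple[int, int]:
    """Strand-aware window immediately 5' of the element."""
    if locus.strand == "+":
        return (max(0, locus.start - window), locus.start)
    return (locus.end, locus.end + window)


def detect_l1hs(
    read_pairs: Sequence[tuple[str, str, str]],
    consensus: str,
    genome: Mapping[str, str],
    catalog: Iterable[L1Locus],
    params: Parameters | None = None,
) -> list[DetectionResult]:
    """Mate-anchoring detection of annotated L1Hs loci.

    ``read_pairs`` are (read_id, mate1_seq, mate2_seq). Only catalog
    entries with subfamily L1Hs are considered. One result is emitted
    per locus with at least ``params.min_support`` supporting pairs;
    output is sorted by locus_id and independent of input pair order.
    """
    params = params or Parameters()
    l1hs_loci = [loc for loc in catalog if loc.subfamily == "L1Hs"]
    # Stage 1: anchor mates on the consensus.
    partners: dict[str, str] = {}
    for rid, m1, m2 in read_pairs:
        for mate_idx, (mate, other) in enumerate(((m1, m2), (m2, m1))):
            aln = align_read(
                mate,
                consensus,
                params.max_mm_consensus,
                require_unique=True,
                chrom="consensus",
                read_id=f"{rid}/{mate_idx + 1}",
            )
            if aln is not None and anchor_filter(aln, params.consensus_anchor):
                partners[f"{rid}/{mate_idx + 1}"] = other
    # Stage 2: place the partner mates uniquely on the genome.
    placed = align_reads_to_genome(
        partners, genome, params.max_mm_genome, require_unique=True
    )
    # Stage 3: intersect partner intervals with L1Hs upstream windows.
    support: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for rid in sorted(placed):
        aln = placed[rid]
        for loc in l1hs_loci:
            lo, hi = upstream_window(loc, params.l1hs_upstream_window)
            if aln.chrom == loc.chrom and aln.start < hi and aln.end > lo:
                support[loc.locus_id].append((aln.chrom, aln.start, aln.end))
    return [
        DetectionResult(
            locus_id=lid,
            supporting_pairs=len(support[lid]),
            mate_positions=support[lid],
        )
        for lid in sorted(support)
        if len(support[lid]) >= params.min_support
    ]
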