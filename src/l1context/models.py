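"""Core domain types for locus-level LINE-1 analysis.

All genomic coordinates are 0-based, half-open ([start, end)), the BED
convention. SAM input is converted on read. Strand is ``'+'`` or ``'-'``;
for a full-length L1 the promoter (5'UTR) sits at ``start`` on the plus
strand and at ``end`` on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = ("+", "-")

# Unicode minus sometimes appears in annotation exports; normalise it.
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


def normalize_strand(s: str) -> str:
    try:
        return _STRAND_ALIASES[s]
    except KeyError:
        raise ValueError(f"strand must be '+' or '-', got {s!r}") from None


@dataclass(frozen=True)
class L1Locus:
    """One annotated full-length L1 element.

    ``intact_orf2`` comes from external annotation (e.g. L1Base); it is
    carried through, never computed. ``within_gene`` is unset until gene
    overlap is annotated.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    intact_orf2: bool = False
    within_gene: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.locus_id}: start must be < end ({self.start} >= {self.end})"
            )
        object.__setattr__(self, "strand", normalize_strand(self.strand))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterAnchor:
    """Strand-resolved 5' end of an element (the '5'UTR start site')."""

    chrom: str
    position: int
    strand: str


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned read pair reduced to a genomic fragment.

    ``strand`` is the transcription strand of the fragment (stranded
    library assumed). ``concordant`` marks proper pairing on one
    chromosome; only concordant fragments are counted toward expression.
    """

    chrom: str
    frag_start: int
    frag_end: int
    strand: str
    concordant: bool = True
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.frag_start >= self.frag_end:
            raise ValueError(
                f"fragment {self.source_id!r}: start must be < end "
                f"({self.frag_start} >= {self.frag_end})"
            )

    def five_prime(self) -> int:
        """0-based position of the fragment's 5'-most base."""
        return self.frag_start if self.strand == "+" else self.frag_end - 1


@dataclass
class PeakTrack:
    """One named interval set (ATAC, or one histone mark x replicate).

    Intervals are kept sorted by (chrom, start). ``scores`` aligns with
    ``intervals`` when present.
    """

    track_name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    scores: Optional[list[float]] = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"track {self.track_name}: interval start must be < end "
                    f"({chrom}:{start}-{end})"
                )
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i][0], self.intervals[i][1]),
        )
        self.intervals = [self.intervals[i] for i in order]
        if self.scores is not None:
            self.scores = [self.scores[i] for i in order]


@dataclass(frozen=True)
class MethylationRecord:
    """Counts for one CpG (coordinate of the C, 0-based)."""

    chrom: str
    cpg_position: int
    methylated_count: int
    unmethylated_count: int

    @property
    def coverage(self) -> int:
        return self.methylated_count + self.unmethylated_count


@dataclass(frozen=True)
class Loop:
    """Paired-anchor chromatin interaction (ChIA-PET CTCF or Pol II loop).

    Anchors are canonically ordered (anchor1.start <= anchor2.start) and
    must share a chromosome.
    """

    loop_type: str  # "CTCF" or "POLII"
    anchor1: tuple[str, int, int]
    anchor2: tuple[str, int, int]
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.anchor1[0] != self.anchor2[0]:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor1[1] > self.anchor2[1]:
            a1, a2 = self.anchor1, self.anchor2
            object.__setattr__(self, "anchor1", a2)
            object.__setattr__(self, "anchor2", a1)


# Default activating-mark panel: six marks, each assayed in duplicate.
DEFAULT_MARKS = ("H3K27Ac", "H3K9Ac", "H3K4Me3", "H3K4Me2", "H3K4Me1", "H4K20Me1")


@dataclass
class Parameters:
    """Every numeric convention of the pipeline in one place.

    Defaults encode the analysis conventions: a 20-read expression
    threshold (9 for low-depth libraries, 5 in stimulation mode), a
    symmetric 500 bp ATAC window around the promoter anchor, asymmetric
    500/300 bp histone windows, the first 500 bp of the 5'UTR for CpG
    methylation, a 2 kb downstream extension for read-through counting,
    500 kb CTCF loop search, 700 bp consensus anchoring with <=25/<=3
    mismatch caps for mate-anchored L1Hs detection, and the YY1/RUNX3
    consensus promoter motifs.
    """

    expression_threshold: int = 20
    low_depth_threshold: int = 9
    stimulation_threshold: int = 5
    atac_window: int = 500
    histone_upstream: int = 500
    histone_downstream: int = 300
    meth_window: int = 500
    downstream_ext: int = 2000
    ctcf_search: int = 500_000
    polII_window: int = 500
    consensus_anchor: int = 700
    max_mm_consensus: int = 25
    max_mm_genome: int = 3
    l1hs_upstream_window: int = 1000
    min_support: int = 1
    yy1_motif: str = "AGCCAAGATGGCCGAATAG"
    runx3_motif: str = "TGCATTTCCATCTGAGGTA"
    motif_deletion_threshold: int = 6
    mark_names: tuple[str, ...] = DEFAULT_MARKS
    replicates_per_mark: int = 2
    curation_promoter_start_bp: int = 900
    curation_start_fraction: float = 0.5
    curation_upstream_ratio: float = 0.5
    curation_upstream_flank: int = 1000
    min_locus_length: int = 5500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "atac_window",
            "histone_upstream",
            "histone_downstream",
            "meth_window",
            "ctcf_search",
            "polII_window",
            "consensus_anchor",
            "l1hs_upstream_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.expression_threshold < 1:
            raise ValueError("expression_threshold must be >= 1")
        for motif in (self.yy1_motif, self.runx3_motif):
            if set(motif) - set("ACGT"):
                raise ValueError(f"motif {motif!r} contains non-ACGT characters")

    @property
    def panel_size(self) -> int:
        return len(self.mark_names) * self.replicates_per_mark


def promoter_anchor(locus: L1Locus) -> PromoterAnchor:
    """Strand-resolved coordinate of the element's 5' end."""
    pos = locus.start if locus.strand == "+" else locus.end
    return PromoterAnchor(chrom=locus.chrom, position=pos, strand=locus.strand)


def strand_window(anchor: PromoterAnchor, upstream: int, downstream: int) -> tuple[int, int]:
    """Half-open interval covering ``upstream`` bp 5' and ``downstream`` bp 3'
    of the anchor, strand-aware, clamped at zero."""
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be >= 0")
    if anchor.strand == "+":
        lo, hi = anchor.position - upstream, anchor.position + downstream
    else:
        lo, hi = anchor.position - downstream, anchor.position + upstream
    return (max(0, lo), max(0, hi))


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """>=1 bp shared between two half-open intervals."""
    return a_start < b_end and b_start < a_end
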