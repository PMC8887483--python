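"""Seeded synthetic-data generator with ground-truth labels.

Emulates the per-class structure of the real datasets the pipeline is
designed for: expressed loci draw fragment counts from a negative
binomial centred on 71.2 reads with fragment 5' ends inside the 5'UTR;
passive-transcription loci receive read-through fragments originating
upstream of the element; transitional loci are ATAC-positive with zero
fragments; closed loci have neither. ATAC probability per class
defaults to the observed rates (82.72% for expressed loci, ~3% for
closed), per-track activating-mark probabilities are set so expected
promoter mark counts are ~5.91 (expressed) and ~0.21 (unexpressed) out
of 12 tracks, and promoter CpG methylation fractions are drawn from
beta distributions with class means 36.26% and 60.82%. Pol II loops
link expressed-locus promoters to mark-rich enhancer intervals at the
observed 9/10 rate (4/10 transitional, 1/10 unexpressed); CTCF loops
span most loci. WGS read pairs straddle the 5' junction of the L1Hs
loci that are truly present in the simulated sample.

All randomness flows from one seed through per-stage substreams, so
regenerating one stage never perturbs another, and a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .l1hs import revcomp
from .models import (
    DEFAULT_MARKS,
    FragmentRecord,
    L1Locus,
    Loop,
    MethylationRecord,
    PeakTrack,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CLASS_NAMES = ("expressed", "transitional", "passive", "closed")

# Stage indices for the per-stage RNG substreams.
_STAGES = {"catalog": 0, "fragments": 1, "peaks": 2, "loops": 3, "wgs": 4}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic dataset (defaults = the
    conditions the pipeline is validated under)."""

    n_loci: int = 600
    chrom_name: str = "chrS"
    chrom_length: int = 10_000_000
    locus_length: int = 6000
    p_expressed: float = 0.033
    p_transitional: float = 0.06
    p_passive: float = 0.01
    # Expressed/passive fragment counts: negative binomial, mean 71.2,
    # variance (1 + dispersion) * mean.
    nb_mean: float = 71.2
    nb_dispersion: float = 0.5
    fragment_length_mean: int = 300
    fragment_length_sd: int = 50
    promoter_bp: int = 900
    n_background_fragments: int = 500
    background_discordant_fraction: float = 0.1
    atac_p: dict = field(
        default_factory=lambda: {
            "expressed": 0.8272,
            "transitional": 1.0,
            "passive": 0.2,
            "closed": 0.03,
        }
    )
    mark_p: dict = field(
        default_factory=lambda: {
            "expressed": 5.91 / 12,
            "transitional": 0.25,
            "passive": 0.10,
            "closed": 0.21 / 12,
        }
    )
    meth_mean: dict = field(
        default_factory=lambda: {
            "expressed": 0.3626,
            "transitional": 0.45,
            "passive": 0.6082,
            "closed": 0.6082,
        }
    )
    meth_concentration: float = 5.0
    cpgs_per_promoter: int = 10
    cpg_coverage_mean: float = 20.0
    p_uncovered_promoter: float = 0.02
    ctcf_p: float = 0.9
    polII_p: dict = field(
        default_factory=lambda: {
            "expressed": 0.9,
            "transitional": 0.4,
            "passive": 0.1,
            "closed": 0.1,
        }
    )
    enhancer_rich_p: dict = field(
        default_factory=lambda: {
            "expressed": 0.8,
            "transitional": 0.5,
            "passive": 0.0,
            "closed": 0.0,
        }
    )
    n_l1hs_present: int = 20
    n_l1hs_absent: int = 20
    pairs_per_junction: int = 10
    n_decoy_pairs: int = 100
    read_length: int = 100
    base_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_expressed + self.p_transitional + self.p_passive > 1:
            raise ValueError("class proportions must sum to <= 1")
        probs = (
            list(self.atac_p.values())
            + list(self.mark_p.values())
            + list(self.polII_p.values())
            + [self.base_error_rate]
        )
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGES[stage], self.seed])

    @property
    def class_probs(self) -> list[float]:
        closed = 1.0 - self.p_expressed - self.p_transitional - self.p_passive
        return [self.p_expressed, self.p_transitional, self.p_passive, closed]


@dataclass
class Simulation:
    """All generated inputs plus the ground truth table."""

    config: GeneratorConfig
    loci: list[L1Locus]
    truth: pd.DataFrame
    genome: dict[str, str]
    consensus: str
    fragments: list[FragmentRecord] = field(default_factory=list)
    total_mapped: int = 0
    atac_track: Optional[PeakTrack] = None
    histone_tracks: list[PeakTrack] = field(default_factory=list)
    meth_records: list[MethylationRecord] = field(default_factory=list)
    loops: list[Loop] = field(default_factory=list)
    wgs_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def promoter_sequences(self, length: int = 900) -> dict[str, str]:
        """Strand-aware promoter (5'UTR) sequence per locus."""
        out = {}
        for loc in self.loci:
            seq = self.genome[loc.chrom]
            if loc.strand == "+":
                s = seq[loc.start : loc.start + length]
            else:
                s = revcomp(seq[loc.end - length : loc.end])
            out[loc.locus_id] = s
        return out


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


_BASE_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases at the given rate (always to a different base)."""
    out = arr.copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size).astype(np.uint8)
        out[hits] = _BASES[(_BASE_CODE[out[hits]] + shift) % 4]
    return out


def make_consensus(
    rng: np.random.Generator,
    length: int = 6000,
    yy1: str = "AGCCAAGATGGCCGAATAG",
    runx3: str = "TGCATTTCCATCTGAGGTA",
) -> str:
    """Synthetic L1 consensus: random sequence with the YY1 motif near the
    5' end and the RUNX3 motif inside the 5'UTR."""
    arr = _random_seq(rng, length)
    arr[12 : 12 + len(yy1)] = np.frombuffer(yy1.encode(), dtype=np.uint8)
    arr[500 : 500 + len(runx3)] = np.frombuffer(runx3.encode(), dtype=np.uint8)
    return arr.tobytes().decode()


def generate_catalog(
    config: GeneratorConfig,
) -> tuple[list[L1Locus], pd.DataFrame, dict[str, str], str]:
    """Synthetic chromosome with non-overlapping full-length loci.

    Every locus body carries a mutated copy of the consensus (0.5%
    divergence for L1Hs, 5% for older subfamilies), reverse-complemented
    on minus-strand loci, so promoter motif scanning and junction read
    simulation operate on realistic sequence.
    """
    rng = config.rng("catalog")
    n = config.n_loci
    margin = 3100  # clearance for upstream windows and downstream extensions
    consensus = make_consensus(rng, config.locus_length)
    genome_arr = _random_seq(rng, config.chrom_length)

    if n > 0:
        spacing = config.chrom_length // n
        slack = spacing - config.locus_length - 2 * margin
        if slack < 1:
            raise ValueError(
                "loci cannot be placed without overlap; use a longer chromosome "
                "or fewer loci"
            )
        starts = [
            i * spacing + margin + int(rng.integers(0, slack)) for i in range(n)
        ]
    else:
        starts = []

    classes = [
        CLASS_NAMES[i]
        for i in rng.choice(len(CLASS_NAMES), size=n, p=config.class_probs)
    ]
    strands = ["+" if b else "-" for b in rng.integers(0, 2, size=n)]

    n_l1hs = min(n, config.n_l1hs_present + config.n_l1hs_absent)
    l1hs_idx = sorted(rng.choice(n, size=n_l1hs, replace=False)) if n_l1hs else []
    present_set = set(
        np.asarray(l1hs_idx)[
            rng.permutation(n_l1hs)[: min(config.n_l1hs_present, n_l1hs)]
        ].tolist()
    )

    cons_arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
    loci: list[L1Locus] = []
    rows = []
    for i, start in enumerate(starts):
        end = start + config.locus_length
        is_l1hs = i in set(l1hs_idx)
        subfamily = "L1Hs" if is_l1hs else ("L1PA2" if i % 2 else "L1PA3")
        divergence = 0.005 if is_l1hs else 0.05
        body = _mutate(cons_arr, divergence, rng)
        if strands[i] == "-":
            body = np.frombuffer(
                revcomp(body.tobytes().decode()).encode(), dtype=np.uint8
            )
        genome_arr[start:end] = body
        locus_id = f"L1-{i:04d}"
        loci.append(
            L1Locus(
                locus_id=locus_id,
                chrom=config.chrom_name,
                start=start,
                end=end,
                strand=strands[i],
                subfamily=subfamily,
                intact_orf2=bool(rng.integers(0, 2)),
            )
        )
        rows.append(
            {
                "locus_id": locus_id,
                "chrom": config.chrom_name,
                "start": start,
                "end": end,
                "strand": strands[i],
                "subfamily": subfamily,
                "true_class": classes[i],
                "l1hs_present": bool(is_l1hs and i in present_set),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "chrom",
            "start",
            "end",
            "strand",
            "subfamily",
            "true_class",
            "l1hs_present",
        ],
    )
    genome = {config.chrom_name: genome_arr.tobytes().decode()}
    return loci, truth, genome, consensus


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with variance (1 + dispersion) * mean."""
    r = mean / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def generate_fragments(
    config: GeneratorConfig, truth: pd.DataFrame, loci: Sequence[L1Locus]
) -> tuple[list[FragmentRecord], int]:
    """Stranded concordant fragments per class, plus background.

    Expressed loci: counts ~ NB(mean, dispersion), fragment 5' ends
    uniform in the first ``promoter_bp`` of the element. Passive loci:
    same count model but every fragment originates 200-2500 bp upstream
    and reads through into the body. Transitional and closed loci emit
    nothing. Background fragments fall in inter-locus gaps (some
    discordant). Returns (fragments, total concordant count), and adds a
    ``true_count`` column to ``truth``.
    """
    rng = config.rng("fragments")
    fragments: list[FragmentRecord] = []
    true_counts = []
    serial = 0
    for loc, cls in zip(loci, truth["true_class"]):
        count = 0
        if cls == "expressed":
            count = _nb_draw(rng, config.nb_mean, config.nb_dispersion)
            for _ in range(count):
                off = int(rng.integers(0, config.promoter_bp))
                flen = int(
                    np.clip(
                        rng.normal(config.fragment_length_mean, config.fragment_length_sd),
                        150,
                        600,
                    )
                )
                if loc.strand == "+":
                    s = loc.start + off
                    e = s + flen
                else:
                    e = loc.end - off
                    s = e - flen
                fragments.append(
                    FragmentRecord(loc.chrom, s, e, loc.strand, True, f"rna_{serial}")
                )
                serial += 1
        elif cls == "passive":
            count = _nb_draw(rng, config.nb_mean, config.nb_dispersion)
            for _ in range(count):
                d = int(rng.integers(200, 2500))
                flen = d + int(rng.integers(100, 900))
                if loc.strand == "+":
                    s = loc.start - d
                    e = s + flen
                else:
                    e = loc.end + d
                    s = e - flen
                fragments.append(
                    FragmentRecord(loc.chrom, s, e, loc.strand, True, f"rna_{serial}")
                )
                serial += 1
        true_counts.append(count)
    truth["true_count"] = true_counts

    # Background transcription confined to inter-locus gaps.
    gaps: list[tuple[int, int]] = []
    prev = 0
    for loc in loci:
        if loc.start - 3000 - 700 > prev:
            gaps.append((prev, loc.start - 3000 - 700))
        prev = loc.end + 3000
    if config.chrom_length - 700 > prev:
        gaps.append((prev, config.chrom_length - 700))
    if gaps and config.n_background_fragments:
        widths = np.array([hi - lo for lo, hi in gaps], dtype=float)
        for _ in range(config.n_background_fragments):
            g = int(rng.choice(len(gaps), p=widths / widths.sum()))
            lo, hi = gaps[g]
            s = int(rng.integers(lo, hi))
            flen = int(
                np.clip(
                    rng.normal(config.fragment_length_mean, config.fragment_length_sd),
                    150,
                    600,
                )
            )
            strand = "+" if rng.integers(0, 2) else "-"
            concordant = bool(rng.random() >= config.background_discordant_fraction)
            fragments.append(
                FragmentRecord(
                    loci[0].chrom if loci else config.chrom_name,
                    s,
                    s + flen,
                    strand,
                    concordant,
                    f"bg_{serial}",
                )
            )
            serial += 1
    total_mapped = sum(1 for f in fragments if f.concordant)
    return fragments, total_mapped


def generate_loops(
    config: GeneratorConfig, truth: pd.DataFrame, loci: Sequence[L1Locus]
) -> tuple[list[Loop], list[tuple[tuple[str, int, int], bool]]]:
    """CTCF loops spanning loci and Pol II promoter-enhancer loops.

    Returns (loops, enhancer specs) where each enhancer spec is the
    distal anchor interval and whether it should be decorated as
    mark-rich. Adds ``true_ctcf`` / ``true_polII`` columns to truth.
    """
    rng = config.rng("loops")
    loops: list[Loop] = []
    enhancers: list[tuple[tuple[str, int, int], bool]] = []
    ctcf_flags, polII_flags = [], []
    for loc, cls in zip(loci, truth["true_class"]):
        pos = loc.start if loc.strand == "+" else loc.end
        has_ctcf = bool(rng.random() < config.ctcf_p)
        ctcf_flags.append(has_ctcf)
        if has_ctcf:
            left = max(0, pos - int(rng.integers(50_000, 400_000)))
            right = pos + int(rng.integers(50_000, 400_000))
            loops.append(
                Loop(
                    "CTCF",
                    (loc.chrom, left, left + 1000),
                    (loc.chrom, right, right + 1000),
                    score=float(rng.integers(10, 100)),
                )
            )
        has_polII = bool(rng.random() < config.polII_p[cls])
        polII_flags.append(has_polII)
        if has_polII:
            dist = int(rng.integers(20_000, 100_000))
            sign = 1 if rng.integers(0, 2) else -1
            enh_start = max(2000, pos + sign * dist)
            enhancer = (loc.chrom, enh_start, enh_start + 2000)
            loops.append(
                Loop(
                    "POLII",
                    (loc.chrom, pos - 200, pos + 200),
                    enhancer,
                    score=float(rng.integers(10, 100)),
                )
            )
            rich = bool(rng.random() < config.enhancer_rich_p[cls])
            enhancers.append((enhancer, rich))
    truth["true_ctcf"] = ctcf_flags
    truth["true_polII"] = polII_flags
    return loops, enhancers


def generate_peaks_and_methylation(
    config: GeneratorConfig,
    truth: pd.DataFrame,
    loci: Sequence[L1Locus],
    enhancers: Sequence[tuple[tuple[str, int, int], bool]] = (),
) -> tuple[PeakTrack, list[PeakTrack], list[MethylationRecord]]:
    """ATAC track, activating-mark tracks and the promoter CpG table.

    Adds ``true_atac``, ``true_mark_count`` and ``true_meth_percent``
    (realized percent of methylated CpGs) columns to truth.
    """
    rng = config.rng("peaks")
    track_names = [
        f"{mark}_rep{r}" for mark in DEFAULT_MARKS for r in (1, 2)
    ]
    atac_intervals: list[tuple[str, int, int]] = []
    atac_scores: list[float] = []
    mark_intervals: dict[str, list[tuple[str, int, int]]] = {t: [] for t in track_names}
    meth_records: list[MethylationRecord] = []
    atac_flags, mark_counts, meth_pcts = [], [], []

    for loc, cls in zip(loci, truth["true_class"]):
        anchor = loc.start if loc.strand == "+" else loc.end
        has_atac = cls == "transitional" or bool(rng.random() < config.atac_p[cls])
        atac_flags.append(has_atac)
        if has_atac:
            center = anchor + int(rng.integers(-300, 301))
            half = int(rng.integers(150, 400))
            atac_intervals.append((loc.chrom, max(0, center - half), center + half))
            atac_scores.append(float(rng.integers(10, 1000)))
        hits = rng.random(len(track_names)) < config.mark_p[cls]
        mark_counts.append(int(hits.sum()))
        for name, hit in zip(track_names, hits):
            if hit:
                center = anchor + int(rng.integers(-100, 101))
                mark_intervals[name].append((loc.chrom, center - 150, center + 150))

        # Promoter CpGs: first meth_window bp of the 5'UTR.
        offsets = np.sort(rng.choice(480, size=config.cpgs_per_promoter, replace=False)) + 10
        # Bimodal per-CpG methylation: each CpG is methylated with the class
        # probability; its read-level fraction comes from a high or low beta.
        states = rng.random(config.cpgs_per_promoter) < config.meth_mean[cls]
        conc = config.meth_concentration
        fracs = np.where(
            states,
            rng.beta(0.9 * conc, 0.1 * conc, size=config.cpgs_per_promoter),
            rng.beta(0.1 * conc, 0.9 * conc, size=config.cpgs_per_promoter),
        )
        uncovered = rng.random() < config.p_uncovered_promoter
        meth_calls = []
        for off, frac in zip(offsets, fracs):
            pos = loc.start + int(off) if loc.strand == "+" else loc.end - 1 - int(off)
            cov = 0 if uncovered else 1 + int(rng.poisson(config.cpg_coverage_mean - 1))
            m = int(rng.binomial(cov, frac)) if cov else 0
            meth_records.append(MethylationRecord(loc.chrom, pos, m, cov - m))
            if cov:
                meth_calls.append(m / cov >= 0.5)
        meth_pcts.append(
            100.0 * sum(meth_calls) / len(meth_calls) if meth_calls else np.nan
        )

    for (chrom, s, e), rich in enhancers:
        n_tracks = int(rng.integers(10, 13)) if rich else int(rng.integers(0, 3))
        which = rng.choice(len(track_names), size=n_tracks, replace=False)
        for t in which:
            center = (s + e) // 2 + int(rng.integers(-300, 301))
            mark_intervals[track_names[t]].append((chrom, center - 200, center + 200))

    truth["true_atac"] = atac_flags
    truth["true_mark_count"] = mark_counts
    truth["true_meth_percent"] = meth_pcts
    atac = PeakTrack("ATAC", atac_intervals, atac_scores)
    tracks = [PeakTrack(name, mark_intervals[name]) for name in track_names]
    return atac, tracks, meth_records


def generate_wgs_pairs(
    config: GeneratorConfig,
    truth: pd.DataFrame,
    loci: Sequence[L1Locus],
    genome: dict[str, str],
    consensus: str,
) -> list[tuple[str, str, str]]:
    """Read pairs spanning the 5' junctions of truly present L1Hs loci.

    One mate is the reverse complement of a consensus segment starting
    in the first 550 bp (so it anchors in reverse orientation inside the
    700 bp consensus anchor window); the other is genomic sequence from
    the strand-aware 1 kb upstream flank. Decoy pairs come from
    inter-locus gaps. Bases are substituted at ``base_error_rate``.
    """
    rng = config.rng("wgs")
    rlen = config.read_length
    pairs: list[tuple[str, str, str]] = []
    serial = 0

    def noisy(seq: str) -> str:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        return _mutate(arr, config.base_error_rate, rng).tobytes().decode()

    present = truth[truth["l1hs_present"]]["locus_id"].tolist()
    by_id = {loc.locus_id: loc for loc in loci}
    for lid in present:
        loc = by_id[lid]
        chrom_seq = genome[loc.chrom]
        for _ in range(config.pairs_per_junction):
            c = int(rng.integers(0, 551))
            mate_a = noisy(revcomp(consensus[c : c + rlen]))
            if loc.strand == "+":
                s = int(rng.integers(loc.start - 1000, loc.start - rlen + 1))
            else:
                s = int(rng.integers(loc.end, loc.end + 1000 - rlen + 1))
            flank = chrom_seq[s : s + rlen]
            mate_b = noisy(flank if rng.integers(0, 2) else revcomp(flank))
            pair = (mate_a, mate_b) if rng.integers(0, 2) else (mate_b, mate_a)
            pairs.append((f"p{serial:06d}", pair[0], pair[1]))
            serial += 1

    # Decoys: purely genomic pairs from the gaps between loci.
    gaps: list[tuple[int, int]] = []
    prev = 0
    for loc in loci:
        if loc.start - 1500 - rlen > prev:
            gaps.append((prev, loc.start - 1500 - rlen))
        prev = loc.end + 1500
    chrom = loci[0].chrom if loci else config.chrom_name
    chrom_seq = genome.get(chrom, "")
    if chrom_seq and config.chrom_length - 600 - rlen > prev:
        gaps.append((prev, config.chrom_length - 600 - rlen))
    if gaps:
        widths = np.array([hi - lo for lo, hi in gaps], dtype=float)
        for _ in range(config.n_decoy_pairs):
            g = int(rng.choice(len(gaps), p=widths / widths.sum()))
            lo, hi = gaps[g]
            s = int(rng.integers(lo, hi))
            insert = int(rng.integers(200, 500))
            m1 = noisy(chrom_seq[s : s + rlen])
            m2 = noisy(revcomp(chrom_seq[s + insert : s + insert + rlen]))
            pairs.append((f"p{serial:06d}", m1, m2))
            serial += 1
    return pairs


def simulate(config: GeneratorConfig | None = None) -> Simulation:
    """Run every generator stage in order and return the bundle."""
    config = config or GeneratorConfig()
    loci, truth, genome, consensus = generate_catalog(config)
    sim = Simulation(
        config=config, loci=loci, truth=truth, genome=genome, consensus=consensus
    )
    sim.fragments, sim.total_mapped = generate_fragments(config, truth, loci)
    sim.loops, enhancers = generate_loops(config, truth, loci)
    sim.atac_track, sim.histone_tracks, sim.meth_records = generate_peaks_and_methylation(
        config, truth, loci, enhancers
    )
    sim.wgs_pairs = generate_wgs_pairs(config, truth, loci, genome, consensus)
    return sim


def write_simulation(sim: Simulation, out_dir: str | Path) -> dict[str, Path]:
    """Write every generated input in its standard format plus truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "marks").mkdir(exist_ok=True)
    paths = {
        "catalog": out / "catalog.bed",
        "genome": out / "genome.fa",
        "consensus": out / "consensus.fa",
        "promoters": out / "promoters.fa",
        "fragments": out / "fragments.bedpe",
        "atac": out / "atac.broadPeak",
        "methylation": out / "methylation.tsv",
        "loops": out / "loops.bedpe",
        "wgs_pairs": out / "wgs_pairs.tsv",
        "truth": out / "truth.tsv",
    }
    io_formats.write_locus_catalog(sim.loci, paths["catalog"])
    io_formats.write_fasta(sim.genome, paths["genome"])
    io_formats.write_fasta({"L1_consensus": sim.consensus}, paths["consensus"])
    io_formats.write_fasta(sim.promoter_sequences(), paths["promoters"])
    io_formats.write_fragments_bedpe(sim.fragments, paths["fragments"])
    if sim.atac_track is not None:
        io_formats.write_peaks(sim.atac_track, paths["atac"])
    for track in sim.histone_tracks:
        p = out / "marks" / f"{track.track_name}.broadPeak"
        io_formats.write_peaks(track, p)
        paths[f"mark:{track.track_name}"] = p
    io_formats.write_methylation(sim.meth_records, paths["methylation"])
    io_formats.write_loops(sim.loops, paths["loops"])
    io_formats.write_read_pairs(sim.wgs_pairs, paths["wgs_pairs"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA")
    return paths
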