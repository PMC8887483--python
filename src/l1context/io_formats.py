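"""Readers and writers for every file format the pipeline touches.

BED-family inputs (catalog BED6+, broadPeak, BEDPE, bedGraph-like TSV)
are 0-based half-open and pass through unshifted. SAM is 1-based and is
converted on read. Bismark CpG reports carry 1-based positions and are
converted on read. Writers emit the same dialects so that a write/read
round trip reproduces the objects field-for-field.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    FragmentRecord,
    L1Locus,
    Loop,
    MethylationRecord,
    PeakTrack,
    normalize_strand,
)


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


# ---------------------------------------------------------------------------
# Locus catalog (BED6+: chrom start end locus_id score strand subfamily [orf2])
# ---------------------------------------------------------------------------

def read_locus_catalog(path: str | Path, min_length: int = 5500) -> list[L1Locus]:
    """Read a BED6+ full-length L1 catalog, keeping loci >= ``min_length`` bp.

    Input order is preserved; ``within_gene`` is left unset.
    """
    loci: list[L1Locus] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 7:
                raise ParseError(f"{path}:{lineno}: expected >=7 columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                locus_id, strand, subfamily = f[3], normalize_strand(f[5]), f[6]
                intact = bool(int(f[7])) if len(f) > 7 and f[7] != "." else False
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end - start < min_length:
                continue
            loci.append(
                L1Locus(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    subfamily=subfamily,
                    intact_orf2=intact,
                )
            )
    return loci


def write_locus_catalog(loci: Iterable[L1Locus], path: str | Path) -> None:
    with open(path, "w") as out:
        for loc in loci:
            out.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t0\t"
                f"{loc.strand}\t{loc.subfamily}\t{int(loc.intact_orf2)}\n"
            )


# ---------------------------------------------------------------------------
# Fragments (BEDPE or SAM)
# ---------------------------------------------------------------------------

def read_fragments(path: str | Path, format: str = "BEDPE") -> list[FragmentRecord]:
    """Read aligned read pairs as genomic fragments.

    Each properly paired record becomes one fragment spanning the
    outermost mate coordinates; improperly paired records (including
    mates on different chromosomes) get ``concordant=False`` rather than
    raising.
    """
    fmt = format.upper()
    if fmt == "BEDPE":
        return _read_fragments_bedpe(path)
    if fmt == "SAM":
        return _read_fragments_sam(path)
    raise ValueError(f"unknown fragment format {format!r}")


def _read_fragments_bedpe(path: str | Path) -> list[FragmentRecord]:
    frags: list[FragmentRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) < 10:
                raise ParseError(f"{path}:{lineno}: BEDPE needs 10 columns, got {len(f)}")
            try:
                c1, s1, e1 = f[0], int(f[1]), int(f[2])
                c2, s2, e2 = f[3], int(f[4]), int(f[5])
                name = f[6]
                strand1, strand2 = f[8], f[9]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            # Stranded FR library: read1's strand is the transcription strand,
            # a concordant pair has opposite mate strands on one chromosome.
            concordant = c1 == c2 and {strand1, strand2} == {"+", "-"}
            if concordant:
                frags.append(
                    FragmentRecord(
                        chrom=c1,
                        frag_start=min(s1, s2),
                        frag_end=max(e1, e2),
                        strand=normalize_strand(strand1),
                        concordant=True,
                        source_id=name,
                    )
                )
            else:
                frags.append(
                    FragmentRecord(
                        chrom=c1,
                        frag_start=s1,
                        frag_end=e1,
                        strand=normalize_strand(strand1) if strand1 in "+-−" else "+",
                        concordant=False,
                        source_id=name,
                    )
                )
    return frags


def _read_fragments_sam(path: str | Path) -> list[FragmentRecord]:
    pairs: dict[str, pysam.AlignedSegment] = {}
    frags: list[FragmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            mate = pairs.pop(read.query_name, None)
            if mate is None:
                pairs[read.query_name] = read
                continue
            read1, read2 = (read, mate) if read.is_read1 else (mate, read)
            chrom = read1.reference_name
            strand = "-" if read1.is_reverse else "+"
            same_chrom = read1.reference_name == read2.reference_name
            concordant = bool(read1.is_proper_pair and read2.is_proper_pair and same_chrom)
            if concordant:
                start = min(read1.reference_start, read2.reference_start)
                end = max(read1.reference_end, read2.reference_end)
            else:
                start, end = read1.reference_start, read1.reference_end
            frags.append(
                FragmentRecord(
                    chrom=chrom,
                    frag_start=start,
                    frag_end=end,
                    strand=strand,
                    concordant=concordant,
                    source_id=read1.query_name,
                )
            )
    # Unpaired leftovers become discordant single-end fragments.
    for name, read in pairs.items():
        frags.append(
            FragmentRecord(
                chrom=read.reference_name,
                frag_start=read.reference_start,
                frag_end=read.reference_end,
                strand="-" if read.is_reverse else "+",
                concordant=False,
                source_id=name,
            )
        )
    return frags


def write_fragments_bedpe(frags: Iterable[FragmentRecord], path: str | Path) -> None:
    """Write fragments as BEDPE read pairs (mates at the fragment ends)."""
    with open(path, "w") as out:
        for fr in frags:
            half = max(1, min(100, (fr.frag_end - fr.frag_start) // 2))
            s1, e1 = fr.frag_start, fr.frag_start + half
            s2, e2 = fr.frag_end - half, fr.frag_end
            if fr.concordant:
                other = "-" if fr.strand == "+" else "+"
                out.write(
                    f"{fr.chrom}\t{s1}\t{e1}\t{fr.chrom}\t{s2}\t{e2}\t"
                    f"{fr.source_id}\t0\t{fr.strand}\t{other}\n"
                )
            else:
                out.write(
                    f"{fr.chrom}\t{s1}\t{e1}\t.\t-1\t-1\t"
                    f"{fr.source_id}\t0\t{fr.strand}\t.\n"
                )


# ---------------------------------------------------------------------------
# Peaks (ENCODE broadPeak or BED3+)
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, track_name: Optional[str] = None) -> PeakTrack:
    """Read a broadPeak (9-column) or BED3+ interval file as one track."""
    name = track_name or Path(path).stem
    intervals: list[tuple[str, int, int]] = []
    scores: list[float] = []
    has_score = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                intervals.append((f[0], int(f[1]), int(f[2])))
                if len(f) >= 5:
                    scores.append(float(f[4]))
                    has_score = True
                else:
                    scores.append(0.0)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakTrack(track_name=name, intervals=intervals, scores=scores if has_score else None)


def write_peaks(track: PeakTrack, path: str | Path) -> None:
    """Write a track as 9-column broadPeak."""
    with open(path, "w") as out:
        for i, (chrom, start, end) in enumerate(track.intervals):
            score = track.scores[i] if track.scores is not None else 0.0
            out.write(
                f"{chrom}\t{start}\t{end}\t{track.track_name}_{i}\t"
                f"{score:g}\t.\t0\t-1\t-1\n"
            )


# ---------------------------------------------------------------------------
# CpG methylation (Bismark CpG report, or 4-column 0-based TSV)
# ---------------------------------------------------------------------------

def read_methylation(path: str | Path) -> list[MethylationRecord]:
    """Read per-CpG methylated/unmethylated counts.

    Two dialects are auto-detected by column count: the Bismark CpG
    report (chrom, 1-based pos, strand, meth, unmeth, context[, tri]) and
    a plain 4-column TSV (chrom, 0-based pos, meth, unmeth).
    """
    records: list[MethylationRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            try:
                if len(f) >= 6:  # Bismark CpG report, 1-based
                    records.append(
                        MethylationRecord(f[0], int(f[1]) - 1, int(f[3]), int(f[4]))
                    )
                elif len(f) == 4:
                    records.append(
                        MethylationRecord(f[0], int(f[1]), int(f[2]), int(f[3]))
                    )
                else:
                    raise ValueError(f"expected 4 or >=6 columns, got {len(f)}")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_methylation(records: Iterable[MethylationRecord], path: str | Path) -> None:
    """Write the 4-column 0-based TSV dialect."""
    with open(path, "w") as out:
        for r in records:
            out.write(
                f"{r.chrom}\t{r.cpg_position}\t{r.methylated_count}\t{r.unmethylated_count}\n"
            )


# ---------------------------------------------------------------------------
# Loops (BEDPE + loop_type column 7, score column 8)
# ---------------------------------------------------------------------------

def read_loops(path: str | Path) -> list[Loop]:
    loops: list[Loop] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) < 7:
                raise ParseError(f"{path}:{lineno}: loop BEDPE needs >=7 columns")
            try:
                loop = Loop(
                    loop_type=f[6].upper(),
                    anchor1=(f[0], int(f[1]), int(f[2])),
                    anchor2=(f[3], int(f[4]), int(f[5])),
                    score=float(f[7]) if len(f) > 7 else None,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            loops.append(loop)
    return loops


def write_loops(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as out:
        for lp in loops:
            c1, s1, e1 = lp.anchor1
            c2, s2, e2 = lp.anchor2
            score = "" if lp.score is None else f"\t{lp.score:g}"
            out.write(f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{lp.loop_type}{score}\n")


# ---------------------------------------------------------------------------
# FASTA and feature tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", quoting=csv.QUOTE_NONE)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_read_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    """Read WGS pairs as a 3-column TSV (read_id, mate1_seq, mate2_seq)."""
    pairs: list[tuple[str, str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            pairs.append((f[0], f[1].upper(), f[2].upper()))
    return pairs


def write_read_pairs(pairs: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for rid, m1, m2 in pairs:
            out.write(f"{rid}\t{m1}\t{m2}\n")
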