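"""Epigenetic categories and prediction for poorly mappable L1Hs loci.

The three headline categories are: *expressed* (robust promoter-driven
transcription), *transitional* (open chromatin — an ATAC peak — but zero
mapped reads), and *unexpressed_closed* (no reads, closed chromatin).
Loci with passive or sub-threshold transcription fall into *other*.

For near-identical L1Hs copies, where unique short-read mapping fails,
expression is predicted from epigenetic context alone: an ATAC peak is a
hard gate, backed by thresholds on activating-mark count and promoter
CpG methylation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .expression import CLASS_EXPRESSED, CLASS_UNEXPRESSED
from .models import FragmentRecord, L1Locus, intervals_overlap

EPI_EXPRESSED = "expressed"
EPI_TRANSITIONAL = "transitional"
EPI_CLOSED = "unexpressed_closed"
EPI_OTHER = "other"

PRED_LIKELY = "likely_expressed"
PRED_INDETERMINATE = "indeterminate"
PRED_UNLIKELY = "unlikely"
PRED_NA = "not_applicable"


def epigenetic_class(expression_class: str, raw_count: int, atac: bool) -> str:
    """Assign expressed / transitional / unexpressed_closed / other."""
    if expression_class == CLASS_EXPRESSED:
        return EPI_EXPRESSED
    if raw_count == 0:
        return EPI_TRANSITIONAL if atac else EPI_CLOSED
    return EPI_OTHER


def reads_with_downstream(
    locus: L1Locus,
    fragments: Iterable[FragmentRecord],
    ext: int = 2000,
) -> int:
    """Concordant sense fragments over the locus body or its strand-aware
    3' extension of ``ext`` bp (captures poly-A read-through into more
    mappable downstream sequence)."""
    if ext < 0:
        raise ValueError("ext must be >= 0")
    if locus.strand == "+":
        lo, hi = locus.start, locus.end + ext
    else:
        lo, hi = max(0, locus.start - ext), locus.end
    return sum(
        1
        for fr in fragments
        if fr.concordant
        and fr.chrom == locus.chrom
        and fr.strand == locus.strand
        and intervals_overlap(fr.frag_start, fr.frag_end, lo, hi)
    )


def predict_l1hs_expression(
    atac: bool,
    mark_count: Optional[int],
    meth_percent: Optional[float],
    panel_size: int = 12,
    marks_min: Optional[int] = None,
    meth_max: float = 50.0,
) -> str:
    """Predict expression of a poorly mappable L1Hs locus from context.

    ``likely_expressed`` requires an ATAC peak, at least ``marks_min``
    activating-mark tracks (default: half the panel) and promoter
    methylation at or below ``meth_max`` percent (unknown methylation
    does not disqualify). No ATAC peak means ``unlikely``; anything else
    is ``indeterminate``.
    """
    if marks_min is None:
        marks_min = panel_size // 2
    if not atac:
        return PRED_UNLIKELY
    marks_ok = mark_count is not None and mark_count >= marks_min
    meth_ok = meth_percent is None or pd.isna(meth_percent) or meth_percent <= meth_max
    if marks_ok and meth_ok:
        return PRED_LIKELY
    return PRED_INDETERMINATE


def classify_loci(
    table: pd.DataFrame,
    fragments: Optional[Sequence[FragmentRecord]] = None,
    catalog: Optional[Sequence[L1Locus]] = None,
    downstream_ext: int = 2000,
    panel_size: int = 12,
    marks_min: Optional[int] = None,
    meth_max: float = 50.0,
) -> pd.DataFrame:
    """Add epigenetic_class, any_reads, l1hs_prediction (L1Hs rows only)
    and, when fragments are given, reads_plus_downstream columns to a
    feature table."""
    required = {"locus_id", "expression_class", "raw_count", "atac", "subfamily"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    out = table.copy()
    out["epigenetic_class"] = [
        epigenetic_class(ec, int(rc), bool(at))
        for ec, rc, at in zip(out["expression_class"], out["raw_count"], out["atac"])
    ]
    out["any_reads"] = out["raw_count"].astype("Int64") >= 1
    mark_counts = out["mark_count"] if "mark_count" in out else pd.Series([None] * len(out))
    meth = out["meth_percent"] if "meth_percent" in out else pd.Series([None] * len(out))
    out["l1hs_prediction"] = [
        predict_l1hs_expression(
            bool(at),
            None if pd.isna(mc) else int(mc),
            None if pd.isna(mp) else float(mp),
            panel_size=panel_size,
            marks_min=marks_min,
            meth_max=meth_max,
        )
        if sub == "L1Hs"
        else PRED_NA
        for at, mc, mp, sub in zip(out["atac"], mark_counts, meth, out["subfamily"])
    ]
    if fragments is not None and catalog is not None:
        by_loc: Mapping[str, L1Locus] = {l.locus_id: l for l in catalog}
        by_key: dict[tuple[str, str], list[FragmentRecord]] = defaultdict(list)
        for fr in fragments:
            if fr.concordant:
                by_key[(fr.chrom, fr.strand)].append(fr)
        out["reads_plus_downstream"] = [
            reads_with_downstream(
                by_loc[lid], by_key[(by_loc[lid].chrom, by_loc[lid].strand)], downstream_ext
            )
            if lid in by_loc
            else pd.NA
            for lid in out["locus_id"]
        ]
    return out
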