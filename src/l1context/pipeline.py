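"""End-to-end driver: inputs -> per-locus feature table with classes.

Thin composition of the stage modules, used by the CLI and by callers
that want the whole analysis in one step.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .classification import classify_loci
from .epigenetics import annotate_epigenetics, build_feature_table
from .expression import call_expression
from .models import (
    FragmentRecord,
    L1Locus,
    Loop,
    MethylationRecord,
    Parameters,
    PeakTrack,
)
from .regulatory import annotate_loops


def run_pipeline(
    catalog: Sequence[L1Locus],
    fragments: Sequence[FragmentRecord],
    atac_track: Optional[PeakTrack] = None,
    histone_tracks: Sequence[PeakTrack] = (),
    meth_records: Iterable[MethylationRecord] = (),
    gene_intervals: Iterable[tuple[str, int, int]] = (),
    loops: Sequence[Loop] = (),
    sample_total_mapped: Optional[int] = None,
    reference_total_mapped: Optional[int] = None,
    threshold: int = 20,
    params: Parameters | None = None,
) -> pd.DataFrame:
    """Expression calling + epigenetic annotation + classification.

    Returns one row per locus with expression counts and class,
    ATAC/mark/methylation features, epigenetic category, L1Hs context
    prediction and (when loops are given) loop/enhancer columns.
    """
    params = params or Parameters()
    expr = call_expression(
        catalog,
        fragments,
        sample_total_mapped=sample_total_mapped,
        reference_total_mapped=reference_total_mapped,
        threshold=threshold,
        params=params,
    )
    epi = annotate_epigenetics(
        catalog,
        atac_track=atac_track,
        histone_tracks=histone_tracks,
        meth_records=meth_records,
        gene_intervals=gene_intervals,
        params=params,
    )
    table = build_feature_table(catalog, expr, epi)
    table = classify_loci(
        table,
        fragments=fragments,
        catalog=catalog,
        downstream_ext=params.downstream_ext,
        panel_size=max(1, len(histone_tracks)) if histone_tracks else params.panel_size,
    )
    if loops:
        mark_counts = {e.locus_id: e.mark_count for e in epi}
        ctx = annotate_loops(catalog, loops, histone_tracks, mark_counts, params)
        loop_df = pd.DataFrame(
            {
                "locus_id": [c.locus_id for c in ctx],
                "in_ctcf_loop": [c.in_ctcf_loop for c in ctx],
                "polII_associated": [c.polII_associated for c in ctx],
                "marks_on_enhancer": [c.marks_on_enhancer for c in ctx],
            }
        )
        table = table.merge(loop_df, on="locus_id", how="left")
    return table
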