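"""Group statistics and report generation.

The comparisons used throughout the analysis are a 2x2 chi-square with
Yates' continuity correction (category proportions, e.g. ATAC-positive
rate among expressed vs unexpressed loci), a two-sided pooled-variance
Student's t-test (per-locus mark counts, methylation percentages, read
counts), and the Pearson product-moment correlation. Statistics are
implemented explicitly from their textbook forms; the test suite checks
them against an independent reference implementation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression import round_half_away


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    n_a: int
    group_b: str
    n_b: int
    statistic_type: str  # chi2_yates | t_test | pearson
    statistic: float
    p_value: float
    mean_a: Optional[float] = None
    mean_b: Optional[float] = None


def chi2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-square for the 2x2 table [[a, b], [c, d]].

    statistic = n * (max(0, |ad - bc| - n/2))^2 / (r1 r2 c1 c2), df = 1.
    Raises on a zero marginal (the statistic is undefined).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined with a zero marginal")
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    stat = n * num * num / (r1 * r2 * c1 * c2)
    return stat, float(sps.chi2.sf(stat, df=1))


def t_test(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> tuple[float, float, float, float]:
    """Two-sided Student's t-test, pooled variance by default.

    Returns (t, p, mean_a, mean_b). With zero pooled variance: equal
    means give p = 1; unequal means give t = +/-inf, p = 0 (degenerate,
    separation is exact).
    """
    x, y = np.asarray(values_a, float), np.asarray(values_b, float)
    na, nb = len(x), len(y)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    ma, mb = float(x.mean()), float(y.mean())
    va, vb = float(x.var(ddof=1)), float(y.var(ddof=1))
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return (0.0, 1.0, ma, mb) if ma == mb else (math.inf, 0.0, ma, mb)
        t = (ma - mb) / math.sqrt(se2)
        df = se2 * se2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if pooled == 0:
            if ma == mb:
                return 0.0, 1.0, ma, mb
            return math.copysign(math.inf, ma - mb), 0.0, ma, mb
        t = (ma - mb) / math.sqrt(pooled * (1 / na + 1 / nb))
        df = na + nb - 2
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), p, ma, mb


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson r, r^2 and the two-sided p from the t-transform."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    n = len(xa)
    if n < 3 or len(ya) != n:
        raise ValueError("need >= 3 paired values")
    xc, yc = xa - xa.mean(), ya - ya.mean()
    sx, sy = float(np.sqrt((xc * xc).sum())), float(np.sqrt((yc * yc).sum()))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, r * r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, r * r, p


def group_summary(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, sample standard deviation, n); stdev is 0 when n = 1."""
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("empty group")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def percent_positive(flags: Sequence[bool] | tuple[int, int]) -> float:
    """Percentage of positives, half-away-from-zero rounded to 2 decimals.

    Accepts either a flag sequence or a (positives, n) pair.
    """
    if isinstance(flags, tuple) and len(flags) == 2:
        pos, n = flags
    else:
        pos, n = sum(bool(f) for f in flags), len(flags)
    if n < 1:
        raise ValueError("need at least one observation")
    return round_half_away(10_000.0 * pos / n) / 100.0


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = {
    "locus_id",
    "expression_class",
    "epigenetic_class",
    "atac",
    "mark_count",
    "meth_percent",
}


def build_report(
    table: pd.DataFrame,
    out_dir: str | Path,
    loop_summary: Optional[pd.DataFrame] = None,
) -> dict:
    """Emit the figure-level TSV sections and a JSON summary.

    Sections: expression/epigenetic class counts, percent ATAC-positive
    per class, mean activating-mark count per class, mean methylation
    per class (loci with no covered CpG excluded), and L1Hs with/without
    ATAC group statistics. Deterministic given the inputs.
    """
    missing = _REPORT_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    class_counts = (
        table.groupby("expression_class").size().rename("n_loci").reset_index()
    ).sort_values("expression_class")
    epi_counts = (
        table.groupby("epigenetic_class").size().rename("n_loci").reset_index()
    ).sort_values("epigenetic_class")

    def per_class(col: str, agg) -> pd.DataFrame:
        rows = []
        for cls, sub in sorted(table.groupby("expression_class")):
            value = agg(sub)
            rows.append({"expression_class": cls, col: value, "n": len(sub)})
        return pd.DataFrame(rows)

    atac_pct = per_class(
        "percent_atac", lambda s: percent_positive((int(s["atac"].sum()), len(s)))
    )
    marks = per_class("mean_mark_count", lambda s: float(s["mark_count"].mean()))
    meth_rows = []
    for cls, sub in sorted(table.groupby("expression_class")):
        vals = sub["meth_percent"].dropna()
        meth_rows.append(
            {
                "expression_class": cls,
                "mean_meth_percent": float(vals.mean()) if len(vals) else float("nan"),
                "n_with_coverage": int(len(vals)),
            }
        )
    meth = pd.DataFrame(meth_rows)

    sections = {
        "class_counts.tsv": class_counts,
        "epigenetic_class_counts.tsv": epi_counts,
        "atac_by_class.tsv": atac_pct,
        "marks_by_class.tsv": marks,
        "methylation_by_class.tsv": meth,
    }

    l1hs = table[table["subfamily"] == "L1Hs"] if "subfamily" in table else table.iloc[0:0]
    if len(l1hs):
        rows = []
        for flag, sub in sorted(l1hs.groupby(l1hs["atac"].astype(bool))):
            row = {
                "atac": bool(flag),
                "n": len(sub),
                "mean_reads": float(sub["raw_count"].mean()),
                "mean_marks": float(sub["mark_count"].mean()),
            }
            if "reads_plus_downstream" in sub:
                vals = sub["reads_plus_downstream"].dropna()
                row["mean_reads_plus_downstream"] = (
                    float(vals.mean()) if len(vals) else float("nan")
                )
            mv = sub["meth_percent"].dropna()
            row["mean_meth_percent"] = float(mv.mean()) if len(mv) else float("nan")
            rows.append(row)
        sections["l1hs_groups.tsv"] = pd.DataFrame(rows)
    if loop_summary is not None:
        sections["loop_summary.tsv"] = loop_summary

    for name, df in sections.items():
        df.to_csv(out / name, sep="\t", index=False, na_rep="NA", float_format="%.6g")

    summary = {
        "n_loci": int(len(table)),
        "class_counts": {
            str(k): int(v)
            for k, v in table["expression_class"].value_counts().sort_index().items()
        },
        "epigenetic_class_counts": {
            str(k): int(v)
            for k, v in table["epigenetic_class"].value_counts().sort_index().items()
        },
        "sections": sorted(sections),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
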