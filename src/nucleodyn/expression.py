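"""Gene-level post-processing: DEG filtering, gene-versus-LAD geometry, and
the Gini coefficient as a transcriptional-divergence measure.

Differential-expression records are filtered with strict thresholds
(adjusted P < 0.01 and |log2 fold change| > 1 by default) and compared with
a merged LAD interval track using the three classic interval semantics:
coverage (bp overlap), closest (gap to the nearest LAD, 0 when
overlapping), and the relative-distance statistic (position of a gene
midpoint between consecutive LAD midpoints, in [0, 0.5]; uniformly placed
features average 0.25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, merge_intervals


@dataclass
class DegRecord:
    gene: str
    log2_fc: float
    padj: float
    interval: GenomicInterval
    direction: str                 # "up" | "down"

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError("adjusted P must be in [0, 1]")


@dataclass
class LadClassRecord:
    gene: str
    within_lad: bool
    overlap_bp: int
    distance_bp: float             # 0 if overlapping; inf if no LAD on chrom
    rel_dist: float | None = None  # in [0, 0.5]; None if not flanked


@dataclass
class GiniResult:
    coefficient: float
    n: int
    variant: str


# --------------------------------------------------------------------------
# DEG filtering
# --------------------------------------------------------------------------

DEG_COLUMNS = {"gene": "gene", "log2_fc": "log2FoldChange", "padj": "padj",
               "chrom": "chrom", "start": "start", "end": "end"}


def filter_degs(
    table: pd.DataFrame,
    padj_max: float = 0.01,
    abs_lfc_min: float = 1.0,
    columns: dict[str, str] | None = None,
    one_based: bool = False,
) -> list[DegRecord]:
    """Keep records with adjusted P strictly below ``padj_max`` and
    |log2 fold change| strictly above ``abs_lfc_min``."""
    cols = dict(DEG_COLUMNS)
    if columns:
        cols.update(columns)
    missing = [cols[k] for k in ("gene", "log2_fc", "padj", "chrom", "start", "end")
               if cols[k] not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    out: list[DegRecord] = []
    for _, row in table.iterrows():
        lfc = float(row[cols["log2_fc"]])
        padj = float(row[cols["padj"]])
        if not (padj < padj_max and abs(lfc) > abs_lfc_min):
            continue
        start = int(row[cols["start"]]) - (1 if one_based else 0)
        iv = GenomicInterval(str(row[cols["chrom"]]), start, int(row[cols["end"]]))
        out.append(DegRecord(str(row[cols["gene"]]), lfc, padj, iv,
                             "up" if lfc > 0 else "down"))
    return out


# --------------------------------------------------------------------------
# gene-vs-LAD geometry
# --------------------------------------------------------------------------

def classify_genes_vs_lads(
    genes: Sequence[GenomicInterval],
    lads: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> list[LadClassRecord]:
    """Coverage/closest semantics against merged LADs.

    A gene is within-LAD iff its bp overlap with merged LADs is at least
    ``min_overlap_bp`` (default: any overlap). Distance is 0 when
    overlapping, else the bp gap to the nearest same-chromosome LAD;
    infinity when the chromosome carries no LAD.
    """
    merged = merge_intervals(list(lads)) if lads else []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[LadClassRecord] = []
    for g in genes:
        ivs = by_chrom.get(g.chrom, [])
        ov = 0
        gap = math.inf
        for iv in ivs:
            ov += max(0, min(g.end, iv.end) - max(g.start, iv.start))
            if iv.end <= g.start:
                gap = min(gap, g.start - iv.end)
            elif iv.start >= g.end:
                gap = min(gap, iv.start - g.end)
            else:
                gap = 0.0
        within = ov >= min_overlap_bp
        dist = 0.0 if ov > 0 else gap
        out.append(LadClassRecord(g.name or f"{g.chrom}:{g.start}-{g.end}",
                                  within, ov, dist))
    return out


def relative_distance(
    genes: Sequence[GenomicInterval],
    lads: Sequence[GenomicInterval],
    n_hist_bins: int = 10,
):
    """Relative-distance statistic of gene midpoints against LAD midpoints.

    For a gene midpoint lying between two consecutive LAD midpoints the
    statistic is min(d_left, d_right) / (d_left + d_right) in [0, 0.5];
    genes outside the flanked span are excluded with a None entry. Returns
    (per-gene list, histogram counts over [0, 0.5]).
    """
    merged = merge_intervals(list(lads)) if lads else []
    mids: dict[str, np.ndarray] = {}
    for iv in merged:
        mids.setdefault(iv.chrom, [])
    for iv in merged:
        mids[iv.chrom].append(iv.midpoint)
    mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
    stats: list[float | None] = []
    for g in genes:
        m = mids.get(g.chrom)
        if m is None or len(m) < 2:
            stats.append(None)
            continue
        x = g.midpoint
        k = np.searchsorted(m, x)
        if k == 0 or k == len(m):
            stats.append(None)
            continue
        d_left = x - m[k - 1]
        d_right = m[k] - x
        stats.append(float(min(d_left, d_right) / (d_left + d_right)))
    vals = np.array([s for s in stats if s is not None])
    hist, _ = np.histogram(vals, bins=n_hist_bins, range=(0.0, 0.5))
    return stats, hist


def tally_degs_by_lad(
    deg_records: Sequence[DegRecord],
    class_records: Sequence[LadClassRecord],
    by_chromosome: bool = False,
) -> pd.DataFrame:
    """Count DEGs by LAD class and direction (optionally per chromosome),
    with percentages of the DEG total per class."""
    classes = {c.gene: c for c in class_records}
    missing = [d.gene for d in deg_records if d.gene not in classes]
    if missing:
        raise ValueError(f"genes without a LAD class record: {missing}")
    rows = []
    for d in deg_records:
        c = classes[d.gene]
        rows.append({
            "gene": d.gene,
            "lad_class": "within" if c.within_lad else "outside",
            "direction": d.direction,
            "chrom": d.interval.chrom,
        })
    df = pd.DataFrame(rows, columns=["gene", "lad_class", "direction", "chrom"])
    keys = ["lad_class", "direction"] + (["chrom"] if by_chromosome else [])
    if df.empty:
        counts = pd.DataFrame(columns=keys + ["n", "pct_of_degs"])
    else:
        counts = df.groupby(keys, as_index=False).size().rename(columns={"size": "n"})
        counts["pct_of_degs"] = 100.0 * counts["n"] / len(df)
    return counts


# --------------------------------------------------------------------------
# Gini coefficient
# --------------------------------------------------------------------------

def gini(values, variant: str = "population") -> GiniResult:
    """Gini coefficient of a non-negative vector.

    Population form G = sum_ij |x_i - x_j| / (2 n^2 mean(x)), computed via
    the sorted-rank identity G = (2 sum_i i*x_(i)) / (n sum x) - (n+1)/n
    (O(n log n), algebraically equal to the double sum). The sample variant
    multiplies by n / (n - 1).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a non-empty 1D vector")
    if np.any(x < 0):
        raise ValueError("values must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for an all-zero vector")
    n = len(x)
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    g = 2.0 * np.dot(ranks, xs) / (n * total) - (n + 1.0) / n
    if variant == "population":
        pass
    elif variant == "sample":
        if n < 2:
            raise ValueError("sample variant needs n >= 2")
        g *= n / (n - 1.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return GiniResult(float(g), n, variant)
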