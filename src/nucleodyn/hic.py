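"""LAD-aware contact matrix analytics.

Contact probability follows a power law P(N) ~ N^-s in genomic separation
N; the exponent magnitude |s| is fitted by ordinary least squares on the
log-log curve over a fixed window (default 1e5 to 1e6 bp). Bins are labeled
LAD or non-LAD from a DamID interval track, and contacts are stratified by
anchor classes: both anchors in LADs, both outside, or one of each
("cross"). Interchromosomal change matrices, the compartment eigenvector of
the observed/expected correlation matrix, the |s|-versus-LAD-coverage
exponential fit, and TAD-size summaries within/outside LADs round out the
module; domain calls themselves are an input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import ContactMatrixFile, GenomicInterval, merge_intervals


@dataclass
class BinLabels:
    """Per-bin LAD membership at a given overlap threshold."""

    is_lad: np.ndarray
    min_overlap: float
    resolution: int


@dataclass
class ScalingCurve:
    """Mean contact frequency on a log-spaced genomic-distance grid."""

    distance_bp: np.ndarray     # bin centers (geometric mean of edges)
    p: np.ndarray               # NaN where no qualifying pairs
    n_pairs: np.ndarray
    segment_class: str


@dataclass
class ScalingFit:
    s_abs: float
    intercept: float
    r_squared: float
    n_min_bp: float
    n_max_bp: float
    n_points: int


@dataclass
class TransChangeMatrix:
    pairs: list[tuple[str, str]]
    pct_change: np.ndarray       # NaN where control mean is 0


@dataclass
class EigvecTrack:
    values: np.ndarray
    sign_convention: str


@dataclass
class DomainSummary:
    classes: np.ndarray          # True = within LAD
    sizes_bp: np.ndarray
    n_lad: int
    n_nonlad: int
    mean_size_lad_bp: float
    mean_size_nonlad_bp: float
    median_size_lad_bp: float
    median_size_nonlad_bp: float


# --------------------------------------------------------------------------
# labeling and coverage
# --------------------------------------------------------------------------

def label_bins(
    lads: Sequence[GenomicInterval],
    chrom: str,
    n_bins: int,
    resolution: int,
    min_overlap: float = 0.5,
) -> BinLabels:
    """Label a bin LAD iff its bp overlap with merged LADs is at least
    ``min_overlap * resolution``."""
    merged = [iv for iv in merge_intervals(list(lads)) if iv.chrom == chrom]
    chrom_end = n_bins * resolution
    for iv in merged:
        if iv.end > chrom_end:
            raise ValueError(
                f"LAD {iv.chrom}:{iv.start}-{iv.end} beyond chromosome extent"
            )
    cover = np.zeros(n_bins)
    for iv in merged:
        b0 = iv.start // resolution
        b1 = (iv.end - 1) // resolution
        for b in range(b0, b1 + 1):
            lo = b * resolution
            hi = lo + resolution
            cover[b] += max(0, min(iv.end, hi) - max(iv.start, lo))
    return BinLabels(cover >= min_overlap * resolution, min_overlap, resolution)


def lad_coverage(
    lads: Sequence[GenomicInterval], chrom_sizes: dict[str, int]
) -> dict[str, float]:
    """Merged LAD bp / chromosome bp, per chromosome in ``chrom_sizes``."""
    merged = merge_intervals(list(lads)) if lads else []
    cov = {c: 0 for c in chrom_sizes}
    for iv in merged:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        cov[iv.chrom] += len(iv)
    return {c: cov[c] / chrom_sizes[c] for c in chrom_sizes}


# --------------------------------------------------------------------------
# P(s) curves and exponent fits
# --------------------------------------------------------------------------

def log_distance_edges(
    resolution: int, n_bins: int, bins_per_decade: int = 8
) -> np.ndarray:
    """Log-spaced genomic-distance bin edges spanning 1..(n_bins-1) bins."""
    lo = np.log10(resolution)
    hi = np.log10((n_bins - 1) * resolution)
    n_edges = max(2, int(np.ceil((hi - lo) * bins_per_decade)) + 1)
    return np.logspace(lo, hi, n_edges)


def scaling_curve(
    matrix: ContactMatrixFile,
    labels: BinLabels | None,
    segment_class: str = "all",
    distance_edges: np.ndarray | str | None = None,
    bins_per_decade: int = 8,
) -> ScalingCurve:
    """Mean contact frequency per log-spaced distance bin, restricted to
    anchor pairs of a segment class.

    The mean at each distance bin divides the summed counts over qualifying
    pairs by the number of qualifying pairs (zero-count pairs included in
    the denominator), so sparse sampling does not bias P upward. The
    reported abscissa is the pair-weighted geometric mean of the diagonal
    separations inside each bin, which keeps log-log fits nearly unbiased.
    Pass ``distance_edges="diagonal"`` for one bin per diagonal (no
    aggregation; exact on noiseless power laws). Diagonal excluded.
    """
    if not matrix.is_cis:
        raise ValueError("scaling curves are defined for cis matrices")
    if segment_class not in ("all", "LAD", "nonLAD", "cross"):
        raise ValueError(f"unknown segment class {segment_class!r}")
    n_bins = matrix.n_bins
    res = matrix.resolution
    if segment_class != "all":
        if labels is None:
            raise ValueError("segment-classified curves need bin labels")
        is_lad = labels.is_lad
        if len(is_lad) != n_bins:
            raise ValueError("label vector length != matrix bins")
    if distance_edges is None:
        distance_edges = log_distance_edges(res, n_bins, bins_per_decade)

    # per-diagonal sums of counts and number of qualifying pairs
    d_all = np.arange(1, n_bins)
    sum_by_d = np.zeros(n_bins)
    off = matrix.bin_j != matrix.bin_i
    bi, bj, ct = matrix.bin_i[off], matrix.bin_j[off], matrix.count[off]
    if segment_class == "all":
        qual = np.ones(len(bi), dtype=bool)
        pairs_by_d = (n_bins - d_all).astype(float)
    else:
        a, b = is_lad[bi], is_lad[bj]
        if segment_class == "LAD":
            qual = a & b
        elif segment_class == "nonLAD":
            qual = ~a & ~b
        else:
            qual = a ^ b
        # count qualifying pairs per diagonal from the label sequence
        pairs_by_d = np.zeros(n_bins - 1)
        lad_f = is_lad.astype(float)
        non_f = 1.0 - lad_f
        for d in d_all:
            x, y = lad_f[:-d], lad_f[d:]
            if segment_class == "LAD":
                pairs_by_d[d - 1] = float((x * y).sum())
            elif segment_class == "nonLAD":
                pairs_by_d[d - 1] = float(((1 - x) * (1 - y)).sum())
            else:
                pairs_by_d[d - 1] = float((x * (1 - y) + (1 - x) * y).sum())
        pairs_by_d = np.concatenate([pairs_by_d])
    np.add.at(sum_by_d, (bj - bi)[qual], ct[qual])
    sums = sum_by_d[1:]

    d_bp = d_all.astype(float) * res
    if isinstance(distance_edges, str):
        if distance_edges != "diagonal":
            raise ValueError(f"unknown distance binning {distance_edges!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(pairs_by_d > 0, sums / pairs_by_d, np.nan)
        return ScalingCurve(d_bp, p, pairs_by_d, segment_class)

    # aggregate diagonals into log-spaced distance bins
    which = np.clip(np.searchsorted(distance_edges, d_bp, side="right") - 1,
                    0, len(distance_edges) - 2)
    in_range = (d_bp >= distance_edges[0]) & (d_bp <= distance_edges[-1])
    n_dist = len(distance_edges) - 1
    bin_sum = np.zeros(n_dist)
    bin_pairs = np.zeros(n_dist)
    bin_logd = np.zeros(n_dist)
    np.add.at(bin_sum, which[in_range], sums[in_range])
    np.add.at(bin_pairs, which[in_range], pairs_by_d[in_range])
    np.add.at(bin_logd, which[in_range],
              (pairs_by_d * np.log(d_bp))[in_range])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(bin_pairs > 0, bin_sum / bin_pairs, np.nan)
        centers = np.where(bin_pairs > 0, np.exp(bin_logd / bin_pairs),
                           np.sqrt(distance_edges[:-1] * distance_edges[1:]))
    return ScalingCurve(centers, p, bin_pairs, segment_class)


def fit_exponent(
    curve: ScalingCurve, n_min: float = 1e5, n_max: float = 1e6
) -> ScalingFit:
    """OLS of log P on log N over [n_min, n_max]; |s| = -slope."""
    sel = (
        (curve.distance_bp >= n_min)
        & (curve.distance_bp <= n_max)
        & np.isfinite(curve.p)
        & (curve.p > 0)
        & (curve.n_pairs > 0)
    )
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 populated distance bins in [{n_min:g}, {n_max:g}] bp, "
            f"found {int(sel.sum())}"
        )
    x = np.log(curve.distance_bp[sel])
    y = np.log(curve.p[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return ScalingFit(float(-slope), float(intercept), float(r2),
                      n_min, n_max, int(sel.sum()))


def fit_coverage_exponential(
    coverages: np.ndarray, exponents: np.ndarray
) -> tuple[float, float, float]:
    """Fit y = a * exp(-b * x) for |s| against LAD coverage.

    Log-linearized least squares seeds a nonlinear refinement. Returns
    (a, b, residual_norm).
    """
    x = np.asarray(coverages, dtype=float)
    y = np.asarray(exponents, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(y <= 0):
        raise ValueError("exponents must be positive for the exponential fit")
    b0, loga0 = np.polyfit(x, np.log(y), 1)
    p0 = (float(np.exp(loga0)), float(-b0))
    popt, _ = curve_fit(lambda t, a, b: a * np.exp(-b * t), x, y, p0=p0,
                        maxfev=10000)
    a, b = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(y - a * np.exp(-b * x)))
    return a, b, resid


# --------------------------------------------------------------------------
# trans contacts
# --------------------------------------------------------------------------

def trans_change(
    control_pairs: dict[tuple[str, str], ContactMatrixFile],
    treated_pairs: dict[tuple[str, str], ContactMatrixFile],
    depth_normalize: bool = False,
) -> TransChangeMatrix:
    """Percent change in mean trans contact frequency per chromosome pair,
    100 * (mean_treated - mean_control) / mean_control.

    With ``depth_normalize`` each condition's entries are first divided by
    that condition's grand total across all pairs (library-depth guard).
    """
    keys = sorted(control_pairs)
    if sorted(treated_pairs) != keys:
        raise ValueError("conditions must share the same chromosome pairs")
    ctrl_tot = sum(m.total for m in control_pairs.values()) if depth_normalize else 1.0
    trt_tot = sum(m.total for m in treated_pairs.values()) if depth_normalize else 1.0
    pct = np.full(len(keys), np.nan)
    for idx, key in enumerate(keys):
        mc, mt = control_pairs[key], treated_pairs[key]
        n_entries_c = (mc.n_bins_a or 0) * (mc.n_bins_b or 0)
        n_entries_t = (mt.n_bins_a or 0) * (mt.n_bins_b or 0)
        if n_entries_c == 0 or n_entries_t == 0:
            raise ValueError(f"pair {key}: matrix extents unknown")
        mean_c = mc.total / ctrl_tot / n_entries_c
        mean_t = mt.total / trt_tot / n_entries_t
        if mean_c > 0:
            pct[idx] = 100.0 * (mean_t - mean_c) / mean_c
    return TransChangeMatrix(keys, pct)


# --------------------------------------------------------------------------
# compartment eigenvector
# --------------------------------------------------------------------------

def compartment_eigenvector(
    matrix: ContactMatrixFile,
    reference_track: np.ndarray | None = None,
    min_populated: int = 10,
) -> EigvecTrack:
    """First eigenvector of the correlation matrix of the O/E-transformed
    cis contacts.

    Expected counts are the per-distance means over populated bins; the
    Pearson correlation matrix of O/E columns is eigendecomposed and the
    eigenvector of the largest-magnitude eigenvalue returned, unit-norm.
    The sign is oriented to correlate positively with ``reference_track``
    (e.g. gene density) when given, else so the first nonzero entry is
    positive.
    """
    if not matrix.is_cis:
        raise ValueError("compartment eigenvector is defined for cis matrices")
    dense = matrix.to_dense()
    n = dense.shape[0]
    populated = dense.sum(axis=0) > 0
    if populated.sum() < max(min_populated, 3):
        raise ValueError(f"need at least {max(min_populated, 3)} populated bins")
    sub = dense[np.ix_(populated, populated)]
    m = sub.shape[0]
    # observed / expected with expected = mean at each separation
    idx = np.arange(m)
    sep = np.abs(idx[:, None] - idx[None, :])
    expected = np.array([sub[sep == d].mean() for d in range(m)])
    if np.all(expected[0] == expected):
        raise ValueError("degenerate (constant) matrix")
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected[sep] > 0, sub / expected[sep], 0.0)
    sd = oe.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate matrix: constant O/E column")
    corr = np.corrcoef(oe, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    lead = int(np.argmax(np.abs(evals)))
    v = evecs[:, lead]
    full = np.zeros(n)
    full[populated] = v
    full /= np.linalg.norm(full)
    if reference_track is not None:
        ref = np.asarray(reference_track, dtype=float)
        if len(ref) != n:
            raise ValueError("reference track length != bins")
        if np.dot(full, ref - ref.mean()) < 0:
            full = -full
        convention = "reference-correlated"
    else:
        nz = np.nonzero(full)[0]
        if len(nz) and full[nz[0]] < 0:
            full = -full
        convention = "first-nonzero-positive"
    return EigvecTrack(full, convention)


# --------------------------------------------------------------------------
# domain summaries
# --------------------------------------------------------------------------

def domain_lad_summary(
    domains: Sequence[GenomicInterval],
    lads: Sequence[GenomicInterval],
    min_overlap: float = 0.5,
) -> DomainSummary:
    """Class each domain LAD iff >= min_overlap of its length overlaps
    merged LADs; summarize counts and sizes per class."""
    merged = merge_intervals(list(lads)) if lads else []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    classes = np.zeros(len(domains), dtype=bool)
    sizes = np.array([float(len(d)) for d in domains])
    for k, dom in enumerate(domains):
        ov = 0
        for iv in by_chrom.get(dom.chrom, []):
            ov += max(0, min(dom.end, iv.end) - max(dom.start, iv.start))
        classes[k] = ov >= min_overlap * len(dom)
    lad_sizes = sizes[classes]
    non_sizes = sizes[~classes]
    return DomainSummary(
        classes, sizes,
        int(classes.sum()), int((~classes).sum()),
        float(lad_sizes.mean()) if len(lad_sizes) else float("nan"),
        float(non_sizes.mean()) if len(non_sizes) else float("nan"),
        float(np.median(lad_sizes)) if len(lad_sizes) else float("nan"),
        float(np.median(non_sizes)) if len(non_sizes) else float("nan"),
    )
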