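"""Synthetic inputs with the statistical structure each analysis assumes.

Every generator has a documented expectation (an analytic moment, a closed
form, or an exact construction) so downstream estimators can be tested as
recovery problems, and a noiseless mode where exact assertions make sense.
Randomness is delivered through named substreams of one global seed: adding
a generator call does not perturb the streams of earlier calls.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .geometry import NucleusMask, normalized_radial_coordinate
from .io_formats import ContactMatrixFile, GenomicInterval, ImageStack, LocalizationTable


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent child stream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# --------------------------------------------------------------------------
# nuclei, radial images, foci, localizations
# --------------------------------------------------------------------------

def gen_nucleus_mask(
    width_px: int,
    height_px: int,
    pixel_size_nm: float,
    semi_axes_nm: tuple[float, float],
    center_px: tuple[float, float] | None = None,
    rotation_deg: float = 0.0,
) -> NucleusMask:
    """A rasterized elliptical nucleus (semi-axes in nm, frame in px)."""
    a_px = semi_axes_nm[0] / pixel_size_nm
    b_px = semi_axes_nm[1] / pixel_size_nm
    if center_px is None:
        center_px = (height_px / 2.0, width_px / 2.0)
    cr, cc = center_px
    th = math.radians(rotation_deg)
    # axis-aligned bounding half-extents of the rotated ellipse
    half_w = math.hypot(a_px * math.cos(th), b_px * math.sin(th))
    half_h = math.hypot(a_px * math.sin(th), b_px * math.cos(th))
    if (cr - half_h < 0 or cr + half_h >= height_px
            or cc - half_w < 0 or cc + half_w >= width_px):
        raise ValueError("ellipse does not fit inside the frame")
    rows, cols = np.mgrid[0:height_px, 0:width_px]
    dr, dc = rows - cr, cols - cc
    u = dc * math.cos(th) + dr * math.sin(th)
    v = -dc * math.sin(th) + dr * math.cos(th)
    raster = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return NucleusMask(raster, pixel_size_nm)


def gen_radial_image(
    mask: NucleusMask,
    profile: Callable[[np.ndarray], np.ndarray],
    total_intensity: float = 1e6,
    noise_model: str = "none",
    seed: int = 0,
):
    """Image whose expected pixel value is proportional to profile(rho).

    With ``noise_model="none"`` intensities sum exactly to
    ``total_intensity``; ``"poisson"`` Poisson-samples each pixel about its
    expectation.
    """
    rho = normalized_radial_coordinate(mask)
    image = np.zeros(mask.raster.shape)
    vals = np.asarray(profile(rho[mask.raster]), dtype=float)
    if np.any(vals < 0):
        raise ValueError("profile must be non-negative")
    if vals.sum() <= 0:
        raise ValueError("profile is identically zero on the mask")
    expected = vals * (total_intensity / vals.sum())
    if noise_model == "none":
        image[mask.raster] = expected
    elif noise_model == "poisson":
        rng = substream(seed, "radial_image")
        image[mask.raster] = rng.poisson(expected).astype(float)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    return image


@dataclass
class FociSet:
    """Point coordinates in nm attached to one nucleus."""

    x: np.ndarray   # nm, column direction
    y: np.ndarray   # nm, row direction
    nucleus_id: str = "nucleus"
    label: str = "locus"

    def __len__(self) -> int:
        return len(self.x)


def gen_foci(
    mask: NucleusMask,
    n: int,
    radial_density: Callable[[np.ndarray], np.ndarray] | str = "uniform_area",
    seed: int = 0,
    n_rho_bins: int = 256,
    label: str = "locus",
) -> FociSet:
    """Place n foci in the mask with a prescribed distribution of rho.

    ``radial_density`` is a probability density of the normalized radius rho
    itself (so uniform placement over the nuclear area corresponds to
    p(rho) = 2*rho, not p = 1 -- the 2*pi*rho area weighting is applied here
    by binning pixels by rho and drawing bins with probability proportional
    to the density mass, then drawing a pixel uniformly within the bin).
    Shorthand strings: "uniform_area" (p = 2 rho), "center" (point mass at
    rho = 0), "boundary" (point mass at rho = 1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = substream(seed, f"foci:{label}")
    rho = normalized_radial_coordinate(mask)
    rows, cols = np.nonzero(mask.raster)
    rho_px = rho[rows, cols]

    if radial_density == "center":
        idx = np.full(n, int(np.argmin(rho_px)))
    elif radial_density == "boundary":
        idx = rng.choice(np.nonzero(rho_px >= rho_px.max() - 1e-12)[0], size=n)
    else:
        dens = (lambda r: 2.0 * r) if radial_density == "uniform_area" else radial_density
        edges = np.linspace(0.0, 1.0, n_rho_bins + 1)
        bin_of = np.clip(np.searchsorted(edges, rho_px, side="right") - 1,
                         0, n_rho_bins - 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mass = np.asarray(dens(centers), dtype=float) * np.diff(edges)
        if np.any(mass < 0):
            raise ValueError("radial_density must be non-negative")
        occupied = np.bincount(bin_of, minlength=n_rho_bins) > 0
        mass = np.where(occupied, mass, 0.0)
        if mass.sum() <= 0:
            raise ValueError("radial_density has no mass over occupied radii")
        chosen_bins = rng.choice(n_rho_bins, size=n, p=mass / mass.sum())
        pixel_lists = [np.nonzero(bin_of == b)[0] for b in range(n_rho_bins)]
        idx = np.array([rng.choice(pixel_lists[b]) for b in chosen_bins])

    # pixel index k spans coordinates [k, k+1) * pixel_size (center k + 0.5)
    jr = rng.uniform(0.0, 1.0, size=n)
    jc = rng.uniform(0.0, 1.0, size=n)
    y_nm = (rows[idx] + jr) * mask.pixel_size_nm
    x_nm = (cols[idx] + jc) * mask.pixel_size_nm
    return FociSet(x_nm, y_nm, mask.id, label)


def gen_localizations(
    mask: NucleusMask,
    n: int,
    periphery_fraction: float,
    periphery_mask: np.ndarray,
    seed: int = 0,
) -> LocalizationTable:
    """SMLM-style events: each lands uniformly in the periphery band with
    probability ``periphery_fraction``, else uniformly in the interior."""
    if not 0.0 <= periphery_fraction <= 1.0:
        raise ValueError("periphery_fraction must be in [0, 1]")
    periphery_mask = np.asarray(periphery_mask, dtype=bool)
    if np.any(periphery_mask & ~mask.raster):
        raise ValueError("periphery_mask must lie inside the nucleus mask")
    if periphery_fraction > 0 and not periphery_mask.any():
        raise ValueError("periphery_mask is empty but periphery_fraction > 0")
    interior = mask.raster & ~periphery_mask
    if periphery_fraction < 1 and not interior.any():
        raise ValueError("interior is empty but periphery_fraction < 1")
    rng = substream(seed, "localizations")
    in_periph = rng.random(n) < periphery_fraction
    pr, pc = np.nonzero(periphery_mask)
    ir, ic = np.nonzero(interior)
    rows = np.empty(n)
    cols = np.empty(n)
    k = int(in_periph.sum())
    if k:
        pick = rng.integers(0, len(pr), size=k)
        rows[in_periph], cols[in_periph] = pr[pick], pc[pick]
    if n - k:
        pick = rng.integers(0, len(ir), size=n - k)
        rows[~in_periph], cols[~in_periph] = ir[pick], ic[pick]
    # events uniform within their source pixel: [k, k+1) * pixel_size
    rows = rows + rng.uniform(0.0, 1.0, size=n)
    cols = cols + rng.uniform(0.0, 1.0, size=n)
    px = mask.pixel_size_nm
    return LocalizationTable(cols * px, rows * px)


# --------------------------------------------------------------------------
# contact maps
# --------------------------------------------------------------------------

def expected_cis_counts(
    n_bins: int,
    resolution: int,
    bin_classes: np.ndarray,
    exponents: dict[str, float],
    scale: float,
):
    """Expected count per (i < j) pair: scale * (|i-j| * resolution)^-s_c.

    Returns (bin_i, bin_j, mu) for the strict upper triangle.
    """
    iu, ju = np.triu_indices(n_bins, k=1)
    d_bp = (ju - iu).astype(float) * resolution
    a_lad = bin_classes[iu]
    b_lad = bin_classes[ju]
    s = np.where(
        a_lad & b_lad, exponents["lad"],
        np.where(~a_lad & ~b_lad, exponents["nonlad"], exponents["cross"]),
    )
    mu = scale * d_bp ** (-s)
    return iu, ju, mu


def gen_cis_contact_map(
    n_bins: int,
    resolution: int,
    lad_layout: Sequence[tuple[int, int]],
    exponents: dict[str, float],
    total_contacts: float | None = 5e6,
    scale: float | None = None,
    noiseless: bool = False,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[ContactMatrixFile, np.ndarray]:
    """Single-chromosome contact map with per-segment power-law decay.

    ``lad_layout`` lists half-open bin ranges labeled LAD; pairs decay as
    d^-s with s chosen by the anchor classes (both-LAD / both-non-LAD /
    cross). ``scale`` is derived from ``total_contacts`` when not given.
    In Poisson mode counts are sampled about their expectations; the
    noiseless mode returns the expectations themselves. Diagonal is zero.
    Returns the matrix and the boolean per-bin LAD labels.
    """
    for key in ("lad", "nonlad", "cross"):
        if key not in exponents:
            raise ValueError(f"exponents must define {key!r}")
        if exponents[key] < 0:
            raise ValueError("exponents must be >= 0")
    classes = np.zeros(n_bins, dtype=bool)
    for lo, hi in lad_layout:
        if not 0 <= lo < hi <= n_bins:
            raise ValueError(f"bad LAD bin range ({lo}, {hi})")
        classes[lo:hi] = True
    if scale is None:
        if total_contacts is None or total_contacts <= 0:
            raise ValueError("give either scale or a positive total_contacts")
        iu, ju, mu = expected_cis_counts(n_bins, resolution, classes,
                                         exponents, scale=1.0)
        scale = total_contacts / mu.sum()
        mu = mu * scale
    else:
        iu, ju, mu = expected_cis_counts(n_bins, resolution, classes,
                                         exponents, scale=scale)
    if noiseless:
        counts = mu
    else:
        counts = substream(seed, "cis_map").poisson(mu).astype(float)
    keep = counts > 0
    matrix = ContactMatrixFile(chrom, chrom, resolution,
                               iu[keep], ju[keep], counts[keep],
                               n_bins_a=n_bins, n_bins_b=n_bins)
    return matrix, classes


def gen_trans_contacts(
    n_bins_a: int,
    n_bins_b: int,
    baseline: float,
    fold_change: float,
    seed: int = 0,
    chrom_a: str = "chrA",
    chrom_b: str = "chrB",
) -> tuple[ContactMatrixFile, ContactMatrixFile]:
    """Paired control/treated interchromosomal blocks: control entries
    Poisson(baseline), treated Poisson(baseline * fold_change)."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = substream(seed, "trans")
    shape = (n_bins_a, n_bins_b)
    ctrl = rng.poisson(baseline, size=shape).astype(float)
    trt = rng.poisson(baseline * fold_change, size=shape).astype(float)

    def pack(dense, ca, cb):
        ii, jj = np.nonzero(dense)
        return ContactMatrixFile(ca, cb, 1, ii, jj, dense[ii, jj],
                                 n_bins_a=n_bins_a, n_bins_b=n_bins_b)

    return pack(ctrl, chrom_a, chrom_b), pack(trt, chrom_a, chrom_b)


# --------------------------------------------------------------------------
# PWS cubes
# --------------------------------------------------------------------------

def gen_temporal_cube(
    mask: NucleusMask,
    frames: int,
    dt_s: float,
    variance: float,
    tau_s: float,
    seed: int = 0,
) -> ImageStack:
    """Per-pixel stationary AR(1) series about a mean of 1.

    Each in-mask pixel follows the exact discretization of an
    Ornstein-Uhlenbeck process: lag-1 coefficient phi = exp(-dt/tau),
    stationary variance = ``variance``, autocorrelation exp(-t/tau).
    Out-of-mask pixels stay constant at 1.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if frames < 10:
        raise ValueError("need at least 10 frames")
    if variance < 0:
        raise ValueError("variance must be >= 0")
    rng = substream(seed, "temporal_cube")
    h, w = mask.raster.shape
    n_px = mask.area_px
    phi = math.exp(-dt_s / tau_s)
    series = np.empty((frames, n_px))
    if variance == 0:
        series[:] = 0.0
    else:
        sd = math.sqrt(variance)
        series[0] = rng.normal(0.0, sd, size=n_px)
        innov_sd = sd * math.sqrt(1.0 - phi * phi)
        eps = rng.normal(0.0, innov_sd, size=(frames - 1, n_px))
        for t in range(1, frames):
            series[t] = phi * series[t - 1] + eps[t - 1]
    cube = np.ones((frames, h, w))
    cube[:, mask.raster] += series
    times = np.arange(frames) * dt_s
    return ImageStack(cube, mask.pixel_size_nm, axis="time", axis_values=times)


def gen_spectral_cube(
    mask: NucleusMask,
    sigma_map: np.ndarray | float,
    wavelengths_nm: np.ndarray | None = None,
    mode: str = "random",
    sine_cycles: int = 3,
    seed: int = 0,
) -> ImageStack:
    """Reference-normalized spectra with mean 1 and prescribed std.

    ``mode="random"`` draws i.i.d. Gaussian fluctuations of std sigma per
    pixel; ``mode="sine"`` writes an integer number of sinusoid cycles of
    amplitude sigma * sqrt(2) so the per-pixel spectral std equals sigma
    exactly (RMS of a sinusoid sampled over whole periods).
    """
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(500.0, 701.0, 2.0)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    n_wl = len(wavelengths_nm)
    if n_wl < 3:
        raise ValueError("wavelength grid must have at least 3 samples")
    sigma = np.broadcast_to(np.asarray(sigma_map, dtype=float), mask.raster.shape)
    if np.any(sigma[mask.raster] < 0):
        raise ValueError("sigma_map must be >= 0 over the mask")
    h, w = mask.raster.shape
    cube = np.ones((n_wl, h, w))
    sig = sigma[mask.raster]
    if mode == "random":
        rng = substream(seed, "spectral_cube")
        cube[:, mask.raster] += rng.normal(size=(n_wl, mask.area_px)) * sig
    elif mode == "sine":
        if (2 * sine_cycles) % n_wl == 0:
            raise ValueError("sine_cycles aliases with the wavelength grid")
        phase = 2.0 * np.pi * sine_cycles * np.arange(n_wl) / n_wl
        cube[:, mask.raster] += np.outer(np.sin(phase), sig * math.sqrt(2.0))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ImageStack(cube, mask.pixel_size_nm, axis="wavelength",
                      axis_values=wavelengths_nm)


# --------------------------------------------------------------------------
# expression tables and gene/LAD layouts
# --------------------------------------------------------------------------

def gen_expression(n_genes: int, lognormal_sigma: float, seed: int = 0) -> np.ndarray:
    """I.i.d. lognormal(0, sigma^2) expression values.

    The population Gini of this law has the closed form erf(sigma / 2),
    which recovery tests use as ground truth.
    """
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    if lognormal_sigma == 0:
        return np.ones(n_genes)
    rng = substream(seed, "expression")
    return rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_genes)


def lognormal_gini(sigma: float) -> float:
    """Population Gini coefficient of lognormal(mu, sigma^2) (mu-free)."""
    return math.erf(sigma / 2.0)


def gen_genes_and_lads(
    genome_bp: int,
    n_lads: int,
    lad_len_bp: int,
    n_genes: int,
    frac_within: float,
    gene_len_bp: int = 2_000,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[list[GenomicInterval], list[GenomicInterval], np.ndarray]:
    """Plant LADs and genes with an exact within-LAD gene fraction.

    LADs are evenly spaced and non-overlapping; exactly
    ``round(frac_within * n_genes)`` genes are placed fully inside LADs and
    the rest strictly in the gaps, with a margin from every boundary so the
    classification is unambiguous. Returns (genes, lads, truth) where truth
    is the boolean within-LAD label per gene.
    """
    if not 0.0 <= frac_within <= 1.0:
        raise ValueError("frac_within must be in [0, 1]")
    pitch = genome_bp // n_lads
    if lad_len_bp >= pitch:
        raise ValueError("LADs would overlap: genome too small")
    margin = max(1, gene_len_bp)
    if lad_len_bp < gene_len_bp + 2 * margin or (pitch - lad_len_bp) < gene_len_bp + 2 * margin:
        raise ValueError("segments too short to place genes with a safety margin")
    rng = substream(seed, "genes_lads")
    lads = [GenomicInterval(chrom, k * pitch, k * pitch + lad_len_bp)
            for k in range(n_lads)]
    n_within = round(frac_within * n_genes)
    truth = np.zeros(n_genes, dtype=bool)
    truth[:n_within] = True
    genes: list[GenomicInterval] = []
    for g in range(n_genes):
        k = int(rng.integers(0, n_lads))
        if truth[g]:
            lo = k * pitch + margin
            hi = k * pitch + lad_len_bp - margin - gene_len_bp
        else:
            lo = k * pitch + lad_len_bp + margin
            hi = (k + 1) * pitch - margin - gene_len_bp
        start = int(rng.integers(lo, hi + 1))
        genes.append(GenomicInterval(chrom, start, start + gene_len_bp,
                                     name=f"gene{g}"))
    return genes, lads, truth
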