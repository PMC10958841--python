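"""Partial-wave spectroscopic (PWS) structural and dynamic statistics.

Structural arm: the per-pixel standard deviation of reference-normalized
spectral interference (Sigma), optionally mapped to the chromatin packing
scaling D through a user-supplied calibration (the physical Sigma -> D
relation is instrument- and model-specific and is deliberately pluggable).

Dynamic arm: per-pixel temporal interference variance Sigma_t^2 from a
single-wavelength time cube; the fractional moving mass m_f obtained by the
physical normalization

    m_f = Sigma_t^2 * (pi rho_0 / (2 Gamma^2 k^3 n_i))
          * (NA_i / NA_c)^2 * (n_1 / (n_m - n_1))^2

with rho_0 the dry density of a nucleosome, k the illumination scalar
wavenumber, n_i / n_1 / n_m the immersion, nuclear and nucleosome refractive
indices, NA_i / NA_c the illumination and collection numerical apertures and
Gamma the Fresnel intensity coefficient at normal incidence (no accepted
default -- it must be supplied); and a diffusion proxy from the decay rate
of the per-pixel temporal autocorrelation. Regional aggregation averages
valid pixels over the boundary-anchored ribbon partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import RibbonSet
from .io_formats import ImageStack


@dataclass(frozen=True)
class OpticalConstants:
    """Physical constants of the dual-PWS normalization (CGS-style units).

    gamma (the Fresnel intensity coefficient) has no accepted default and
    must be given; ``fresnel_intensity_coefficient`` computes it from an RI
    pair if desired.
    """

    gamma: float
    rho0_g_cm3: float = 0.55     # dry density of a nucleosome
    k_cm1: float = 1.57e5        # illumination scalar wavenumber
    n_i: float = 1.518           # immersion oil RI
    n_1: float = 1.37            # nuclear RI
    n_m: float = 1.43            # nucleosome RI
    na_i: float = 0.52           # illumination NA
    na_c: float = 1.49           # collection NA

    def __post_init__(self) -> None:
        for name in ("gamma", "rho0_g_cm3", "k_cm1", "n_i", "n_1", "n_m",
                     "na_i", "na_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_m <= self.n_1:
            raise ValueError("n_m must exceed n_1")

    @property
    def moving_mass_prefactor_g(self) -> float:
        """The constant C in m_f = C * Sigma_t^2 (grams)."""
        return (
            (math.pi * self.rho0_g_cm3 / (2.0 * self.gamma**2 * self.k_cm1**3 * self.n_i))
            * (self.na_i / self.na_c) ** 2
            * (self.n_1 / (self.n_m - self.n_1)) ** 2
        )


def fresnel_intensity_coefficient(n_a: float, n_b: float) -> float:
    """Normal-incidence Fresnel intensity (reflectance) coefficient
    ((n_a - n_b) / (n_a + n_b))^2 for a user-chosen RI pair."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("refractive indices must be positive")
    return ((n_a - n_b) / (n_a + n_b)) ** 2


# --------------------------------------------------------------------------
# structural arm
# --------------------------------------------------------------------------

def compute_sigma(cube: ImageStack, reference_spectrum: np.ndarray | float = 1.0
                  ) -> np.ndarray:
    """Per-pixel population std of reference-normalized spectral intensity.

    The cube is divided by the reference spectrum wavelength-wise, the
    per-pixel spectral mean removed, and the population standard deviation
    over wavelength returned.
    """
    if cube.data.ndim != 3 or cube.axis != "wavelength":
        raise ValueError("need a spectral cube with a wavelength axis")
    if cube.data.shape[0] < 3:
        raise ValueError("need at least 3 wavelength samples")
    ref = np.asarray(reference_spectrum, dtype=float)
    if ref.ndim == 0:
        ref = np.full(cube.data.shape[0], float(ref))
    if np.any(ref == 0):
        raise ValueError("reference spectrum contains zeros")
    norm = cube.data / ref[:, None, None]
    return norm.std(axis=0, ddof=0)


def sigma_to_d(sigma_map: np.ndarray, calibration) -> np.ndarray:
    """Map Sigma to packing scaling D with a pluggable calibration.

    ``calibration`` is ``None``/``"identity"``, an ``(a, b)`` affine pair
    applied as a * Sigma + b, or a tabulated monotone curve given as
    ``(sigma_grid, d_grid)`` (linearly interpolated; the grid must be
    strictly monotone in sigma and monotone in d).
    """
    sigma_map = np.asarray(sigma_map, dtype=float)
    if calibration is None or calibration == "identity":
        return sigma_map.copy()
    a, b = calibration
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 0:
        return float(a) * sigma_map + float(b)
    if np.any(np.diff(a) <= 0):
        raise ValueError("calibration sigma grid must be strictly increasing")
    db = np.diff(b)
    if not (np.all(db >= 0) or np.all(db <= 0)):
        raise ValueError("calibration table must be monotone")
    return np.interp(sigma_map, a, b)


# --------------------------------------------------------------------------
# dynamic arm
# --------------------------------------------------------------------------

def temporal_variance(cube: ImageStack, reference: float = 1.0) -> np.ndarray:
    """Per-pixel population variance over frames (Sigma_t^2) of
    reference-normalized intensity."""
    if cube.data.ndim != 3 or cube.axis != "time":
        raise ValueError("need a temporal cube with a time axis")
    if cube.data.shape[0] < 10:
        raise ValueError("need at least 10 frames")
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return (cube.data / reference).var(axis=0, ddof=0)


def fractional_moving_mass(
    sigma_t2_map: np.ndarray, constants: OpticalConstants
) -> tuple[np.ndarray, float]:
    """m_f map (grams) and the prefactor used: m_f = C * Sigma_t^2."""
    c = constants.moving_mass_prefactor_g
    return np.asarray(sigma_t2_map, dtype=float) * c, c


@dataclass
class DiffusionResult:
    """Per-pixel ACF decay rates with a validity flag map.

    ``rate_s1`` is 1/tau from the single-exponential fit of the normalized
    autocovariance; pixels whose lag-1 ACF is non-positive (noise-dominated)
    are flagged invalid and excluded from regional means. ``diffusion`` is
    rate times an optional user conversion constant (defaults to 1, i.e.
    the decay rate itself is reported).
    """

    rate_s1: np.ndarray
    diffusion: np.ndarray
    valid: np.ndarray
    fit_lags: int


def _acf_per_pixel(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocovariance for each column of (frames, n_px)."""
    x = series - series.mean(axis=0)
    var = (x * x).mean(axis=0)
    var = np.where(var > 0, var, np.nan)
    T = x.shape[0]
    acf = np.empty((max_lag + 1, x.shape[1]))
    for lag in range(max_lag + 1):
        acf[lag] = (x[: T - lag] * x[lag:]).sum(axis=0) / (T * var)
    return acf


def diffusion_map(
    cube: ImageStack,
    dt_s: float | None = None,
    fit_lags: int = 10,
    mask: np.ndarray | None = None,
    conversion: float = 1.0,
) -> DiffusionResult:
    """ACF-decay rate per pixel from a single-wavelength temporal cube.

    The normalized autocovariance over the first ``fit_lags`` lags is fitted
    with exp(-t/tau) by ordinary least squares on log-transformed positive
    ACF values (through the origin, since acf(0) = 1); the decay rate 1/tau
    in s^-1 is returned. Pixels with non-positive lag-1 ACF are flagged.
    """
    if cube.data.ndim != 3 or cube.axis != "time":
        raise ValueError("need a temporal cube with a time axis")
    frames = cube.data.shape[0]
    if frames < 50:
        raise ValueError("need at least 50 frames for ACF fitting")
    if fit_lags < 3:
        raise ValueError("fit_lags must be >= 3")
    if dt_s is None:
        av = cube.axis_values
        dt_s = float(av[1] - av[0])
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    h, w = cube.data.shape[1:]
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    series = cube.data[:, mask]
    acf = _acf_per_pixel(series, fit_lags)

    rate = np.full(series.shape[1], np.nan)
    valid_px = np.isfinite(acf[1]) & (acf[1] > 0)
    lags = np.arange(1, fit_lags + 1) * dt_s
    a = acf[1:, valid_px]
    logs = np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), np.nan)
    # per-pixel OLS through the origin of log acf on -t over positive lags
    wts = np.isfinite(logs)
    t = lags[:, None] * np.ones_like(logs)
    num = np.nansum(np.where(wts, -t * logs, 0.0), axis=0)
    den = np.nansum(np.where(wts, t * t, 0.0), axis=0)
    ok = den > 0
    r = np.full(a.shape[1], np.nan)
    r[ok] = num[ok] / den[ok]
    rate[valid_px] = r
    valid_px &= np.isfinite(rate) & (rate > 0)

    rate_map = np.full((h, w), np.nan)
    valid_map = np.zeros((h, w), dtype=bool)
    rate_map[mask] = rate
    valid_map[mask] = valid_px
    return DiffusionResult(rate_map, rate_map * conversion, valid_map, fit_lags)


# --------------------------------------------------------------------------
# regional aggregation
# --------------------------------------------------------------------------

@dataclass
class RegionalResult:
    """Mean map value per ribbon region (1 = periphery ... center last)."""

    region_labels: np.ndarray          # 1..n_ribbons+1
    means: np.ndarray                  # NaN where no valid pixels
    n_valid: np.ndarray
    n_excluded: np.ndarray
    pct_change: np.ndarray | None = None


def regional_dynamics(
    value_map: np.ndarray,
    ribbons: RibbonSet,
    paired_map: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    paired_valid: np.ndarray | None = None,
) -> RegionalResult:
    """Average a per-pixel map over ribbon regions; optionally compute the
    percent change of a paired (treated) map against this (control) map,
    100 * (treated - control) / control per region."""
    value_map = np.asarray(value_map, dtype=float)
    if value_map.shape != ribbons.labels.shape:
        raise ValueError("map and ribbon labels must share a frame")
    n_regions = ribbons.n_ribbons + 1
    region_ids = np.arange(1, n_regions + 1)

    def region_means(vmap, vmask):
        ok = np.isfinite(vmap)
        if vmask is not None:
            ok &= np.asarray(vmask, dtype=bool)
        means = np.full(n_regions, np.nan)
        nv = np.zeros(n_regions, dtype=int)
        nx = np.zeros(n_regions, dtype=int)
        for idx, rid in enumerate(region_ids):
            sel = ribbons.labels == rid
            good = sel & ok
            nv[idx] = int(good.sum())
            nx[idx] = int(sel.sum()) - nv[idx]
            if nv[idx]:
                means[idx] = float(vmap[good].mean())
        return means, nv, nx

    means, nv, nx = region_means(value_map, valid)
    pct = None
    if paired_map is not None:
        pmeans, _, _ = region_means(np.asarray(paired_map, dtype=float),
                                    paired_valid)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (pmeans - means) / means
    return RegionalResult(region_ids, means, nv, nx, pct)
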