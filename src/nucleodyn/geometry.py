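"""Spatial partitions of a segmented nucleus.

All radial analyses in the pipeline run on partitions derived from a binary
nucleus mask: ten concentric rings of equal normalized radius (with the
``2k - 1`` annulus-area weight attached), six boundary-anchored ribbons of
fixed physical width plus a central remainder, a dilated-contour periphery
band with its complementary interior, and the centroid / circular-equivalent
radius used to normalize focus distances.

The normalized radial coordinate is defined from the Euclidean distance
transform: ``rho = 1 - d_b / max(d_b)`` where ``d_b`` is a pixel's distance
to the background. On a disk this reduces to r/R; on lobed or blebbed nuclei
it follows the shape rather than assuming ellipticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class NucleusMask:
    """Binary nucleus raster with physical pixel size.

    The foreground must be a single connected component; interior holes are
    filled on construction (partitions must tile the full nuclear area).
    """

    raster: np.ndarray
    pixel_size_nm: float
    id: str = "nucleus"

    def __post_init__(self) -> None:
        raster = np.asarray(self.raster).astype(bool)
        if raster.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if not raster.any():
            raise ValueError("mask is empty")
        n_comp = ndimage.label(raster)[1]
        if n_comp != 1:
            raise ValueError(f"mask must be a single component, found {n_comp}")
        self.raster = ndimage.binary_fill_holes(raster)

    @property
    def area_px(self) -> int:
        return int(self.raster.sum())

    @property
    def area_nm2(self) -> float:
        return self.area_px * self.pixel_size_nm**2


@dataclass
class RadialRingSet:
    """Concentric ring labels 1..K (1 most central, K most peripheral)."""

    labels: np.ndarray
    areas_px: np.ndarray        # area of ring k at index k-1
    weights: np.ndarray         # 2k - 1 annulus-area idealization
    K: int


@dataclass
class RibbonSet:
    """Boundary-anchored ribbons 1..n (1 abuts the boundary) + center.

    The center region carries label ``n_ribbons + 1``.
    """

    labels: np.ndarray
    areas_px: np.ndarray
    n_ribbons: int
    width_nm: float

    @property
    def center_label(self) -> int:
        return self.n_ribbons + 1


@dataclass
class PeripheryInteriorMasks:
    periphery: np.ndarray
    interior: np.ndarray
    iterations: int
    kernel: int


@dataclass
class CentroidRadius:
    centroid_px: tuple[float, float]   # (row, col)
    centroid_nm: tuple[float, float]
    radius_nm: float


def boundary_distance_px(mask: NucleusMask) -> np.ndarray:
    """Distance (px) from each foreground pixel to the nearest background
    pixel, shifted so boundary pixels sit at 0."""
    d = ndimage.distance_transform_edt(mask.raster)
    d[mask.raster] -= 1.0
    return d


def normalized_radial_coordinate(mask: NucleusMask) -> np.ndarray:
    """Per-pixel rho in [0, 1]: 0 at the deepest interior point, 1 at the
    boundary. Background pixels are NaN."""
    d = ndimage.distance_transform_edt(mask.raster)
    d_ref = d.max()
    if d_ref <= 0:
        raise ValueError("mask has no interior")
    rho = np.full(mask.raster.shape, np.nan)
    rho[mask.raster] = 1.0 - d[mask.raster] / d_ref
    return rho


def make_rings(mask: NucleusMask, K: int = 10) -> RadialRingSet:
    """Partition the mask into K bins of equal normalized radius.

    Ring k collects pixels with rho in [(k-1)/K, k/K); the outermost bin is
    closed so the partition is exact. The annulus-area weight 2k - 1 (exact
    for a disk cut into equal-radius rings) is attached for downstream
    occupancy normalization.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rho = normalized_radial_coordinate(mask)
    labels = np.zeros(mask.raster.shape, dtype=np.int32)
    inside = mask.raster
    k_of = np.minimum((rho[inside] * K).astype(int) + 1, K)
    labels[inside] = k_of
    areas = np.bincount(labels[inside], minlength=K + 1)[1:]
    if np.any(areas == 0):
        empty = int(np.argmin(areas)) + 1
        raise ValueError(
            f"ring {empty} is empty: K={K} exceeds the mask's radial depth in pixels"
        )
    weights = 2 * np.arange(1, K + 1) - 1
    return RadialRingSet(labels, areas.astype(np.int64), weights.astype(float), K)


def make_ribbons(
    mask: NucleusMask,
    width_nm: float = 260.0,
    n_ribbons: int = 6,
) -> RibbonSet:
    """Boundary-anchored ribbons of fixed physical width plus a center.

    Ribbon j collects pixels whose boundary distance lies in
    [(j-1)*w, j*w) nm; everything deeper is the center region (label
    ``n_ribbons + 1``). Errors if the center would be empty.
    """
    if width_nm <= 0:
        raise ValueError("width_nm must be positive")
    if n_ribbons < 0:
        raise ValueError("n_ribbons must be >= 0")
    d_nm = boundary_distance_px(mask) * mask.pixel_size_nm
    labels = np.zeros(mask.raster.shape, dtype=np.int32)
    inside = mask.raster
    j = (d_nm[inside] // width_nm).astype(int) + 1
    j = np.minimum(j, n_ribbons + 1)
    labels[inside] = j
    areas = np.bincount(labels[inside], minlength=n_ribbons + 2)[1:]
    if n_ribbons > 0 and areas[-1] == 0:
        raise ValueError(
            "center region is empty; use fewer or narrower ribbons for this nucleus"
        )
    return RibbonSet(labels, areas.astype(np.int64), n_ribbons, width_nm)


def boundary_contour(mask: NucleusMask) -> np.ndarray:
    """Foreground pixels 8-adjacent to background (outer boundary kept
    inside the nucleus)."""
    eroded = ndimage.binary_erosion(
        mask.raster, structure=np.ones((3, 3), bool), border_value=0
    )
    return mask.raster & ~eroded


def make_periphery_interior(
    mask: NucleusMask, iterations: int = 5, kernel: int = 5
) -> PeripheryInteriorMasks:
    """Periphery = boundary contour dilated ``iterations`` times with a
    ``kernel x kernel`` all-ones structuring element, clipped to the mask;
    interior = the remainder. Each dilation grows the band by
    (kernel - 1) / 2 px in the Chebyshev metric.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be a positive odd size")
    contour = boundary_contour(mask)
    periphery = contour
    if iterations > 0:
        periphery = ndimage.binary_dilation(
            contour, structure=np.ones((kernel, kernel), bool), iterations=iterations
        )
    periphery = periphery & mask.raster
    interior = mask.raster & ~periphery
    if not interior.any():
        import warnings

        warnings.warn("interior mask is empty after dilation", stacklevel=2)
    return PeripheryInteriorMasks(periphery, interior, iterations, kernel)


def centroid_and_radius(mask: NucleusMask) -> CentroidRadius:
    """Foreground centroid and the radius of the circle of equal area."""
    rows, cols = np.nonzero(mask.raster)
    cr, cc = float(rows.mean()), float(cols.mean())
    # physical coordinates place pixel centers at (index + 0.5) * pixel_size
    r_nm = float(np.sqrt(mask.area_nm2 / np.pi))
    return CentroidRadius(
        (cr, cc),
        ((cr + 0.5) * mask.pixel_size_nm, (cc + 0.5) * mask.pixel_size_nm),
        r_nm,
    )
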