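"""Fovea and optic-nerve-head landmark detection.

The fovea is located as the centroid of the minimum of the ILM–GCL
thickness map (the foveal depression), the ONH as a RANSAC circle fit to
the edge of the dark disc in the adaptively-thresholded SLO image.  Both
landmarks anchor the inter-patient normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import GridSpec, LayerSurfaces, SloImage

__all__ = [
    "FoveaDetection",
    "OnhDetection",
    "LandmarkSet",
    "detect_fovea",
    "detect_fovea_from_surfaces",
    "detect_onh",
    "fit_circle_ransac",
    "circumcircle",
]


@dataclass
class FoveaDetection:
    position_mm: np.ndarray
    low_confidence: bool = False


@dataclass
class OnhDetection:
    found: bool
    center_mm: np.ndarray | None = None
    radius_mm: float | None = None
    n_inliers: int = 0


@dataclass
class LandmarkSet:
    """Fovea + ONH landmarks of one eye, in the eye's en-face frame (mm)."""

    fovea: np.ndarray
    onh_center: np.ndarray
    onh_radius: float
    verified: bool = False

    def __post_init__(self):
        self.fovea = np.asarray(self.fovea, dtype=float)
        self.onh_center = np.asarray(self.onh_center, dtype=float)
        if self.onh_radius <= 0:
            raise ValueError("onh_radius must be positive")
        if np.allclose(self.fovea, self.onh_center):
            raise ValueError("fovea and ONH center must differ")


def detect_fovea(
    ilm: np.ndarray,
    gcl: np.ndarray,
    spacing_um: tuple[float, float],
    origin_mm: tuple[float, float] = (0.0, 0.0),
    tol_um: float = 2.0,
) -> FoveaDetection:
    """Centroid of the ILM–GCL minimum-thickness region.

    The thickness map is median-smoothed (3×3) and all pixels within
    ``tol_um`` of the global minimum form the foveal region whose
    unweighted centroid is returned in physical mm.  A region covering
    more than half the field (no discernible pit) is flagged low
    confidence.

    ``spacing_um`` is (bscan, ascan) spacing; arrays are (bscan, ascan).
    """
    thick = np.asarray(gcl, dtype=float) - np.asarray(ilm, dtype=float)
    if not np.isfinite(thick).any():
        raise ValueError("thickness map has no finite values")
    smooth = ndimage.median_filter(thick, size=3)
    tmin = np.nanmin(smooth)
    region = smooth <= tmin + tol_um
    rows, cols = np.nonzero(region)
    grid = GridSpec(
        shape=thick.shape, spacing_um=(spacing_um[1], spacing_um[0]), origin_mm=origin_mm
    )
    centroid = grid.pixel_to_mm(cols.mean(), rows.mean())
    low_conf = region.mean() > 0.5
    return FoveaDetection(position_mm=np.asarray(centroid, dtype=float), low_confidence=low_conf)


def detect_fovea_from_surfaces(surfaces: LayerSurfaces, tol_um: float = 2.0) -> FoveaDetection:
    return detect_fovea(
        surfaces["ILM"],
        surfaces["RNFL_GCL"],
        spacing_um=surfaces.spacing_um,
        origin_mm=surfaces.origin_mm,
        tol_um=tol_um,
    )


def circumcircle(p1, p2, p3) -> tuple[np.ndarray, float] | None:
    """Circle through three points; None when they are collinear."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(ax - ux, ay - uy))


def _kasa_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares circle fit (exact through 3 points)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = np.sqrt(c + cx**2 + cy**2)
    return np.array([cx, cy]), float(r)


def fit_circle_ransac(
    points: np.ndarray,
    tol: float = 2.0,
    n_iter: int = 1000,
    radius_bounds: tuple[float, float] | None = None,
    min_inliers: int = 3,
    seed: int = 0,
) -> OnhDetection:
    """RANSAC circle fit over candidate edge points.

    3-point minimal samples; the circle with maximal inlier support
    (|distance to center - radius| <= tol) is refit by least squares on
    its inliers.  Units follow the input points.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return OnhDetection(found=False)
    rng = np.random.default_rng(seed)
    best_inliers = None
    best_count = 0
    for _ in range(n_iter):
        i, j, k = rng.choice(len(pts), size=3, replace=False)
        cc = circumcircle(pts[i], pts[j], pts[k])
        if cc is None:
            continue
        center, r = cc
        if radius_bounds is not None and not (radius_bounds[0] <= r <= radius_bounds[1]):
            continue
        d = np.abs(np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]) - r)
        inliers = d <= tol
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
    if best_inliers is None or best_count < min_inliers:
        return OnhDetection(found=False)
    center, r = _kasa_fit(pts[best_inliers])
    return OnhDetection(found=True, center_mm=center, radius_mm=r, n_inliers=best_count)


def detect_onh(
    slo: SloImage,
    block_px: int = 31,
    offset: float = 5.0,
    tol_px: float = 2.0,
    n_iter: int = 1000,
    radius_bounds_mm: tuple[float, float] = (0.5, 1.3),
    min_inliers: int = 25,
    seed: int = 0,
) -> OnhDetection:
    """Detect the ONH disc in an SLO image.

    The image is adaptively thresholded (local mean over a
    ``block_px``-sized window minus a small offset; the ONH is the dark
    class), the dark-region edge pixels are extracted, and a RANSAC
    circle constrained to anatomically plausible radii is fit.  Returns
    an "ONH not found" result (``found=False``) when inlier support is
    insufficient — distinguishable from an exception.
    """
    img = slo.values.astype(float)
    local_mean = ndimage.uniform_filter(img, size=block_px)
    dark = img < local_mean - offset
    # vessels are thin dark structures; an opening with a disc wider than
    # a vessel calibre (~0.25 mm) keeps only disc-like dark regions
    r_open = max(int(round(125.0 / slo.spacing_um)), 1)
    yy, xx = np.mgrid[-r_open : r_open + 1, -r_open : r_open + 1]
    disc = xx**2 + yy**2 <= r_open**2
    dark = ndimage.binary_opening(dark, structure=disc)
    edge = dark & ~ndimage.binary_erosion(dark)
    rows, cols = np.nonzero(edge)
    if len(rows) < 3:
        return OnhDetection(found=False)
    px_mm = slo.spacing_um / 1000.0
    res = fit_circle_ransac(
        np.column_stack([cols, rows]).astype(float),
        tol=tol_px,
        n_iter=n_iter,
        radius_bounds=(radius_bounds_mm[0] / px_mm, radius_bounds_mm[1] / px_mm),
        min_inliers=min_inliers,
        seed=seed,
    )
    if not res.found:
        return res
    center = slo.grid.pixel_to_mm(res.center_mm[0], res.center_mm[1])
    return OnhDetection(
        found=True,
        center_mm=np.asarray(center, dtype=float),
        radius_mm=res.radius_mm * px_mm,
        n_inliers=res.n_inliers,
    )
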