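"""Per-visit en-face features: layer thickness and choroidal texture.

Thickness maps are per-A-scan axial distances between two boundary
surfaces, in µm.  Because choroidal segmentation is unreliable at low
signal levels, the choroid is additionally characterized by gray-level
co-occurrence (GLCM) Haralick descriptors of a small sub-Bruch's-membrane
patch per A-scan: Energy, Entropy, Inverse Difference Moment, Inertia,
Cluster Shade and Cluster Prominence, averaged over four pixel-pair
offsets (horizontal, vertical and the two diagonals, distances chosen to
compensate the axial/lateral anisotropy of the voxel grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EnfaceMap, LayerSurfaces, OctVolume

__all__ = [
    "DEFAULT_OFFSETS",
    "TEXTURE_NAMES",
    "GLCMatrix",
    "TextureDescriptors",
    "thickness_map",
    "extract_choroid_patch",
    "compute_glcm",
    "haralick",
    "choroid_texture_maps",
]

#: (dx lateral, dz axial) pixel-pair offsets: 1 px lateral ≈ 6 px axial in
#: physical distance for the phantom voxel anisotropy.
DEFAULT_OFFSETS = ((1, 0), (0, 6), (1, 6), (1, -6))

TEXTURE_NAMES = (
    "energy",
    "entropy",
    "inverse_difference_moment",
    "inertia",
    "cluster_shade",
    "cluster_prominence",
)


@dataclass
class GLCMatrix:
    """Normalized, symmetrized co-occurrence probabilities (bins × bins)."""

    probabilities: np.ndarray
    empty: bool = False

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")


@dataclass
class TextureDescriptors:
    energy: float
    entropy: float
    inverse_difference_moment: float
    inertia: float
    cluster_shade: float
    cluster_prominence: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TEXTURE_NAMES])


def thickness_map(surfaces: LayerSurfaces, top: str, bottom: str) -> EnfaceMap:
    """Per-A-scan axial distance bottom − top in µm.

    Both surfaces sample the same A-scan, so the Euclidean distance
    between the two boundary points reduces to the axial distance.
    """
    for name in (top, bottom):
        if name not in surfaces:
            raise KeyError(f"surface {name!r} not present")
    values = surfaces[bottom] - surfaces[top]
    spec = surfaces.enface_grid_spec()
    return EnfaceMap(
        values=values,
        spacing_um=spec.spacing_um,
        origin_mm=spec.origin_mm,
        units="um",
    )


def extract_choroid_patch(
    volume: OctVolume,
    bm: np.ndarray,
    bscan: int,
    ascan: int,
    width_px: int = 5,
    depth_um: float = 300.0,
) -> np.ndarray | None:
    """Sub-BM intensity patch for one A-scan: width_px × ceil(depth/dz).

    The patch starts at the BM depth of the central A-scan and extends
    downward; it is clamped laterally at the B-scan borders and truncated
    at the volume bottom.  Returns None (invalid marker) when BM is
    undefined or fewer than 50% of the nominal depth samples fit.
    """
    bm = np.asarray(bm, dtype=float)
    if not np.isfinite(bm[bscan, ascan]):
        return None
    dz = volume.depth_spacing_um
    n_z = int(np.ceil(depth_um / dz))
    z0 = int(np.rint(bm[bscan, ascan] / dz))
    if z0 < 0 or z0 >= volume.n_depth:
        return None
    z1 = min(z0 + n_z, volume.n_depth)
    if (z1 - z0) < 0.5 * n_z:
        return None
    half = width_px // 2
    a0 = max(ascan - half, 0)
    a1 = min(ascan - half + width_px, volume.n_ascan)
    patch = volume.intensities[bscan, a0:a1, z0:z1]
    return np.asarray(patch, dtype=float)


def compute_glcm(
    patch: np.ndarray,
    offsets=DEFAULT_OFFSETS,
    bins: int = 16,
    intensity_range: tuple[float, float] = (0.0, 128.0),
) -> list[GLCMatrix]:
    """One normalized, symmetrized GLCM per pixel-pair offset.

    Intensities are clipped to ``intensity_range`` then binned uniformly
    into ``bins`` levels (the top edge falls into the last bin).  Each
    co-occurring pair is counted in both directions.  An offset larger
    than the patch yields an empty-GLCM marker.
    """
    p = np.asarray(patch, dtype=float)
    if p.ndim != 2:
        raise ValueError("patch must be 2D (lateral, axial)")
    lo, hi = intensity_range
    q = np.clip(p, lo, hi)
    lev = np.minimum(((q - lo) / (hi - lo) * bins).astype(int), bins - 1)
    invalid = ~np.isfinite(p)
    out = []
    for dx, dz in offsets:
        glcm = np.zeros((bins, bins))
        nx, nz = p.shape
        x0, x1 = max(0, -dx), min(nx, nx - dx)
        z0, z1 = max(0, -dz), min(nz, nz - dz)
        if x1 <= x0 or z1 <= z0:
            out.append(GLCMatrix(glcm, empty=True))
            continue
        a = lev[x0:x1, z0:z1]
        b = lev[x0 + dx : x1 + dx, z0 + dz : z1 + dz]
        ok = ~(invalid[x0:x1, z0:z1] | invalid[x0 + dx : x1 + dx, z0 + dz : z1 + dz])
        if not ok.any():
            out.append(GLCMatrix(glcm, empty=True))
            continue
        np.add.at(glcm, (a[ok], b[ok]), 1.0)
        glcm = glcm + glcm.T  # count each pair in both directions
        glcm /= glcm.sum()
        out.append(GLCMatrix(glcm))
    return out


def haralick(glcm: GLCMatrix) -> TextureDescriptors:
    """The six Haralick descriptors of a normalized GLCM.

    entropy uses log base 2 with 0·log 0 := 0; cluster shade and
    prominence are the third and fourth moments of i+j about µx+µy.
    """
    p = glcm.probabilities
    total = p.sum()
    if glcm.empty or total <= 0:
        raise ValueError("cannot compute descriptors of an empty GLCM")
    p = p / total
    n = p.shape[0]
    i, j = np.mgrid[0:n, 0:n]
    energy = float((p**2).sum())
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    inertia = float(((i - j) ** 2 * p).sum())
    mu_x = float((i * p).sum())
    mu_y = float((j * p).sum())
    dev = i + j - mu_x - mu_y
    shade = float((dev**3 * p).sum())
    prominence = float((dev**4 * p).sum())
    return TextureDescriptors(
        energy=energy,
        entropy=entropy,
        inverse_difference_moment=idm,
        inertia=inertia,
        cluster_shade=shade,
        cluster_prominence=prominence,
    )


def choroid_texture_maps(
    volume: OctVolume,
    bm: np.ndarray,
    offsets=DEFAULT_OFFSETS,
    bins: int = 16,
    intensity_range: tuple[float, float] = (0.0, 128.0),
    width_px: int = 5,
    depth_um: float = 300.0,
    stride: int = 1,
) -> dict[str, EnfaceMap]:
    """Six texture maps: per A-scan, patch → GLCMs → descriptors → mean.

    Descriptors are averaged over the (non-empty) offset GLCMs; A-scans
    with an invalid patch yield invalid pixels.  ``stride`` subsamples
    the A-scan grid for speed; skipped pixels are invalid.
    """
    bm = np.asarray(bm, dtype=float)
    if not np.isfinite(bm).any():
        raise ValueError("BM surface is undefined everywhere")
    shape = (volume.n_bscan, volume.n_ascan)
    maps = {name: np.full(shape, np.nan) for name in TEXTURE_NAMES}
    for b in range(0, volume.n_bscan, stride):
        for a in range(0, volume.n_ascan, stride):
            patch = extract_choroid_patch(volume, bm, b, a, width_px, depth_um)
            if patch is None:
                continue
            glcms = [
                g for g in compute_glcm(patch, offsets, bins, intensity_range) if not g.empty
            ]
            if not glcms:
                continue
            desc = np.mean([haralick(g).as_array() for g in glcms], axis=0)
            for name, val in zip(TEXTURE_NAMES, desc):
                maps[name][b, a] = val
    spec = volume.enface_grid_spec()
    return {
        name: EnfaceMap(
            values=vals,
            spacing_um=spec.spacing_um,
            origin_mm=spec.origin_mm,
            units="dimensionless",
            eye_id=volume.eye_id,
            visit_id=volume.visit_id,
            month=volume.month,
        )
        for name, vals in maps.items()
    }
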