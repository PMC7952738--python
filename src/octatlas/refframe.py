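"""Inter-patient normalization into the common fovea-centred atlas grid.

Every eye is mapped rigidly into a 512×512 grid of 15 µm pixels
(7.68 × 7.68 mm): the fovea goes to the grid centre and the eye is
rotated so the fovea→ONH direction makes the population-mean angle of
5.6° with the horizontal, ONH above the horizon.  Right eyes are
mirrored about the vertical axis first so that nasal is +x for every
eye.  A feature map is carried into the atlas by composing the
intra-patient (visit → visit 0) and inter-patient (eye → atlas)
transforms into one resampling.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import AffineTransform2D, RigidTransform2D
from .landmarks import LandmarkSet
from .registration import apply_transform
from .types import AtlasGrid, EnfaceMap

__all__ = [
    "build_normalization_transform",
    "resample_to_atlas",
    "eccentricity_map",
    "fovea_onh_angle_deg",
]


def build_normalization_transform(
    landmarks: LandmarkSet,
    laterality: str,
    target_angle_deg: float = 5.6,
) -> RigidTransform2D:
    """Rigid eye→atlas transform from the fovea and ONH landmarks.

    The fovea maps exactly to the atlas centre (0, 0); after the
    transform the fovea→ONH direction makes ``target_angle_deg`` with
    +x, ONH above the horizontal.  Right eyes (OD) are mirrored before
    the rotation so nasal is +x for all eyes.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    fovea = np.asarray(landmarks.fovea, dtype=float)
    onh = np.asarray(landmarks.onh_center, dtype=float)
    if np.allclose(fovea, onh):
        raise ValueError("fovea and ONH center coincide")
    mirror = laterality == "OD"
    M = np.diag([-1.0, 1.0]) if mirror else np.eye(2)
    d = M @ (onh - fovea)
    phi = math.degrees(math.atan2(d[1], d[0]))
    rot = target_angle_deg - phi
    transform = RigidTransform2D(rotation=rot, mirror=mirror)
    # choose the translation so the fovea lands exactly on the centre
    t_mm = -transform.matrix @ fovea
    return RigidTransform2D(rotation=rot, translation_um=tuple(t_mm * 1000.0), mirror=mirror)


def fovea_onh_angle_deg(transform: RigidTransform2D, landmarks: LandmarkSet) -> float:
    """Angle of the transformed fovea→ONH direction versus the horizon."""
    f, o = transform.apply(np.stack([landmarks.fovea, landmarks.onh_center]))
    return math.degrees(math.atan2(o[1] - f[1], o[0] - f[0]))


def resample_to_atlas(
    enface: EnfaceMap,
    intra: AffineTransform2D | RigidTransform2D | None = None,
    inter: RigidTransform2D | None = None,
    grid: AtlasGrid | None = None,
) -> EnfaceMap:
    """Resample a per-visit map into the atlas grid in one interpolation.

    ``intra`` maps the visit into the eye's own (visit 0) frame,
    ``inter`` the eye frame into the atlas; the two are composed so the
    map is interpolated only once.  Out-of-field pixels are invalid.
    """
    if grid is None:
        grid = AtlasGrid()
    if intra is None:
        intra = AffineTransform2D.identity()
    if isinstance(intra, RigidTransform2D):
        intra = intra.as_affine()
    if inter is None:
        inter = RigidTransform2D.identity()
    total = inter.as_affine().compose(intra)
    return apply_transform(enface, total, grid)


def eccentricity_map(grid: AtlasGrid | None = None) -> EnfaceMap:
    """Per-pixel distance to the atlas centre (fovea), in mm."""
    if grid is None:
        grid = AtlasGrid()
    x, y = grid.coordinate_arrays()
    return EnfaceMap(
        values=np.hypot(x, y),
        spacing_um=grid.spacing_um,
        origin_mm=grid.origin_mm,
        units="mm",
    )
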