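"""File formats: TIFF volumes/maps with JSON sidecars, CSV tables.

Volumes are multi-page 8-bit TIFFs (one page per B-scan); en-face and
atlas maps are 32-bit float single-page TIFFs.  Each image carries a
JSON sidecar (same path with ``.json`` appended) holding spacing,
origin, laterality and visit metadata.  Layer surfaces travel as long
CSV (surface_name, bscan, ascan, depth_um); transforms and landmarks as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import AffineTransform2D, RigidTransform2D
from .landmarks import LandmarkSet
from .types import EnfaceMap, LayerSurfaces, OctVolume, SloImage

__all__ = [
    "save_volume",
    "load_volume",
    "save_enface",
    "load_enface",
    "save_slo",
    "load_slo",
    "save_surfaces",
    "load_surfaces",
    "save_transforms",
    "load_transforms",
    "save_landmarks",
    "load_landmarks",
]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def save_volume(volume: OctVolume, path) -> None:
    path = Path(path)
    data = np.clip(volume.intensities, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data)  # pages = B-scans
    meta = {
        "spacing_um": list(volume.spacing_um),
        "origin_mm": list(volume.origin_mm),
        "laterality": volume.laterality,
        "eye_id": volume.eye_id,
        "visit_id": volume.visit_id,
        "month": volume.month,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_volume(path) -> OctVolume:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path)
    return OctVolume(
        intensities=data.astype(np.float32),
        spacing_um=tuple(meta["spacing_um"]),
        laterality=meta["laterality"],
        eye_id=meta["eye_id"],
        visit_id=meta["visit_id"],
        month=meta["month"],
        origin_mm=tuple(meta["origin_mm"]),
    )


def save_enface(enface: EnfaceMap, path) -> None:
    path = Path(path)
    vals = np.where(enface.valid_mask, enface.values, np.nan).astype(np.float32)
    tifffile.imwrite(path, vals)
    meta = {
        "spacing_um": list(enface.spacing_um),
        "origin_mm": list(enface.origin_mm),
        "units": enface.units,
        "eye_id": enface.eye_id,
        "visit_id": enface.visit_id,
        "group": enface.group,
        "month": enface.month,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_enface(path) -> EnfaceMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    vals = tifffile.imread(path).astype(float)
    return EnfaceMap(
        values=vals,
        spacing_um=tuple(meta["spacing_um"]),
        origin_mm=tuple(meta["origin_mm"]),
        valid_mask=np.isfinite(vals),
        units=meta["units"],
        eye_id=meta["eye_id"],
        visit_id=meta["visit_id"],
        group=meta.get("group", ""),
        month=meta["month"],
    )


def save_slo(slo: SloImage, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.clip(slo.values, 0, 255).astype(np.uint8))
    meta = {"spacing_um": slo.spacing_um, "origin_mm": list(slo.origin_mm)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_slo(path) -> SloImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return SloImage(
        values=tifffile.imread(path).astype(float),
        spacing_um=meta["spacing_um"],
        origin_mm=tuple(meta["origin_mm"]),
    )


def save_surfaces(surfaces: LayerSurfaces, path) -> None:
    rows = []
    for name, depth in surfaces.surfaces.items():
        b, a = np.mgrid[0 : depth.shape[0], 0 : depth.shape[1]]
        rows.append(
            pd.DataFrame(
                {
                    "surface_name": name,
                    "bscan": b.ravel(),
                    "ascan": a.ravel(),
                    "depth_um": depth.ravel(),
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False)
    meta = {"spacing_um": list(surfaces.spacing_um), "origin_mm": list(surfaces.origin_mm)}
    _sidecar(Path(path)).write_text(json.dumps(meta, indent=1))


def load_surfaces(path) -> LayerSurfaces:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(Path(path)).read_text())
    surfaces = {}
    for name, part in df.groupby("surface_name"):
        nb = part["bscan"].max() + 1
        na = part["ascan"].max() + 1
        grid = np.full((nb, na), np.nan)
        grid[part["bscan"], part["ascan"]] = part["depth_um"]
        surfaces[name] = grid
    return LayerSurfaces(
        surfaces=surfaces,
        spacing_um=tuple(meta["spacing_um"]),
        origin_mm=tuple(meta["origin_mm"]),
    )


def _transform_to_dict(t) -> dict:
    if isinstance(t, RigidTransform2D):
        return {
            "type": "rigid",
            "rotation_deg": t.rotation,
            "translation_um": list(t.translation_um),
            "mirror": t.mirror,
        }
    return {
        "type": "affine",
        "linear": np.asarray(t.linear).tolist(),
        "translation_um": list(t.translation_um),
    }


def _transform_from_dict(d) -> RigidTransform2D | AffineTransform2D:
    if d["type"] == "rigid":
        return RigidTransform2D(
            rotation=d["rotation_deg"],
            translation_um=tuple(d["translation_um"]),
            mirror=d["mirror"],
        )
    return AffineTransform2D(linear=np.asarray(d["linear"]), translation_um=tuple(d["translation_um"]))


def save_transforms(transforms: list, path) -> None:
    Path(path).write_text(json.dumps([_transform_to_dict(t) for t in transforms], indent=1))


def load_transforms(path) -> list:
    return [_transform_from_dict(d) for d in json.loads(Path(path).read_text())]


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "fovea_mm": landmarks.fovea.tolist(),
                "onh_center_mm": landmarks.onh_center.tolist(),
                "onh_radius_mm": landmarks.onh_radius,
                "verified": landmarks.verified,
            },
            indent=1,
        )
    )


def load_landmarks(path) -> LandmarkSet:
    d = json.loads(Path(path).read_text())
    return LandmarkSet(
        fovea=np.asarray(d["fovea_mm"]),
        onh_center=np.asarray(d["onh_center_mm"]),
        onh_radius=d["onh_radius_mm"],
        verified=d.get("verified", False),
    )
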