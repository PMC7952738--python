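"""Core data containers for en-face OCT atlas analysis.

Conventions
-----------
* An OCT volume is indexed ``(bscan, ascan, depth)``.  The en-face plane
  maps A-scan index to physical x and B-scan index to physical y, both in
  mm; depth increases from the vitreous downward, in µm.
* 2D maps (:class:`EnfaceMap`, :class:`SloImage`) are indexed ``(row,
  col) = (y, x)``; the physical position of pixel ``(iy, ix)`` is
  ``origin + (ix * sx, iy * sy) / 1000`` with spacing in µm and origin in
  mm.  +x is nasal after laterality mirroring, +y superior.
* Layer boundary surfaces are depth maps in µm from the top of the
  volume, on the ``(bscan, ascan)`` grid, ordered from inner to outer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "OctVolume",
    "EnfaceMap",
    "SloImage",
    "LayerSurfaces",
    "AtlasGrid",
    "SURFACE_ORDER",
    "LAYER_BOUNDS",
]

#: Boundary surfaces from inner to outer.
SURFACE_ORDER = (
    "ILM",
    "RNFL_GCL",
    "IPL_INL",
    "OPL_ONL",
    "ONL_ORB",
    "BM",
    "CHOROID_POST",
)

#: Layers defined as consecutive surface pairs (top, bottom).
LAYER_BOUNDS = {
    "RNFL": ("ILM", "RNFL_GCL"),
    "GCL_IPL": ("RNFL_GCL", "IPL_INL"),
    "INL_OPL": ("IPL_INL", "OPL_ONL"),
    "ONL": ("OPL_ONL", "ONL_ORB"),
    "ORB": ("ONL_ORB", "BM"),
    "CHOROID": ("BM", "CHOROID_POST"),
}


@dataclass
class OctVolume:
    """One OCT acquisition of one eye at one visit.

    ``intensities`` has shape ``(n_bscan, n_ascan, n_depth)`` in device
    units 0–255.  ``spacing_um`` is ``(bscan, ascan, depth)`` spacing in
    µm, ``origin_mm`` the en-face position of A-scan (0, 0).
    """

    intensities: np.ndarray
    spacing_um: tuple[float, float, float]
    laterality: str = "OS"
    eye_id: str = ""
    visit_id: str = ""
    month: float = 0.0
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (bscan, ascan, depth)")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("all spacings must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")

    @property
    def n_bscan(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ascan(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_depth(self) -> int:
        return self.intensities.shape[2]

    @property
    def depth_spacing_um(self) -> float:
        return self.spacing_um[2]

    def enface_grid_spec(self) -> "GridSpec":
        """Grid of the en-face plane: x along A-scans, y along B-scans."""
        return GridSpec(
            shape=(self.n_bscan, self.n_ascan),
            spacing_um=(self.spacing_um[1], self.spacing_um[0]),
            origin_mm=self.origin_mm,
        )


@dataclass(frozen=True)
class GridSpec:
    """Shape + spacing (x, y in µm) + origin (mm) of a 2D pixel grid."""

    shape: tuple[int, int]
    spacing_um: tuple[float, float]
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def pixel_to_mm(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        x = self.origin_mm[0] + np.asarray(cols) * self.spacing_um[0] / 1000.0
        y = self.origin_mm[1] + np.asarray(rows) * self.spacing_um[1] / 1000.0
        return np.stack([x, y], axis=-1)

    def mm_to_pixel(self, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = np.asarray(points_mm, dtype=float)
        cols = (p[..., 0] - self.origin_mm[0]) * 1000.0 / self.spacing_um[0]
        rows = (p[..., 1] - self.origin_mm[1]) * 1000.0 / self.spacing_um[1]
        return cols, rows

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x_mm, y_mm) arrays of shape ``shape``."""
        rows, cols = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        pts = self.pixel_to_mm(cols, rows)
        return pts[..., 0], pts[..., 1]


@dataclass
class EnfaceMap:
    """2D scalar feature map in the en-face plane."""

    values: np.ndarray
    spacing_um: tuple[float, float]
    origin_mm: tuple[float, float] = (0.0, 0.0)
    valid_mask: np.ndarray | None = None
    units: str = "dimensionless"
    eye_id: str = ""
    visit_id: str = ""
    group: str = ""
    month: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask shape mismatch")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape, self.spacing_um, self.origin_mm)

    @property
    def isotropic(self) -> bool:
        return np.isclose(self.spacing_um[0], self.spacing_um[1])

    def with_values(self, values: np.ndarray, **kw) -> "EnfaceMap":
        out = replace(self)
        out.values = np.asarray(values, dtype=float)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class SloImage:
    """Scanning laser ophthalmoscope fundus image sharing the OCT frame."""

    values: np.ndarray
    spacing_um: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape, (self.spacing_um, self.spacing_um), self.origin_mm)


@dataclass
class LayerSurfaces:
    """Named boundary depth maps (µm from volume top) on the A-scan grid."""

    surfaces: dict
    spacing_um: tuple[float, float]  # (bscan, ascan) µm
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        shapes = {np.asarray(v).shape for v in self.surfaces.values()}
        if len(shapes) > 1:
            raise ValueError("all surfaces must share one grid")
        self.surfaces = {k: np.asarray(v, dtype=float) for k, v in self.surfaces.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def __contains__(self, name: str) -> bool:
        return name in self.surfaces

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.surfaces.values())).shape

    def enface_grid_spec(self) -> GridSpec:
        return GridSpec(
            shape=self.shape,
            spacing_um=(self.spacing_um[1], self.spacing_um[0]),
            origin_mm=self.origin_mm,
        )

    def check_ordering(self, atol_um: float = 1e-6) -> bool:
        """True when the named surfaces are depth-ordered everywhere."""
        present = [s for s in SURFACE_ORDER if s in self.surfaces]
        for top, bot in zip(present[:-1], present[1:]):
            if np.any(self.surfaces[bot] - self.surfaces[top] < -atol_um):
                return False
        return True


class AtlasGrid(GridSpec):
    """The common reference grid: 512×512 pixels at 15 µm, fovea centred.

    The fovea sits at pixel (255.5, 255.5); +x points toward the ONH
    (nasal) side, +y superior.  Physical extent is 7.68 × 7.68 mm.
    """

    SIZE = 512
    SPACING_UM = 15.0
    CENTER_PX = (SIZE - 1) / 2.0  # 255.5

    def __init__(self):
        half = self.CENTER_PX * self.SPACING_UM / 1000.0
        super().__init__(
            shape=(self.SIZE, self.SIZE),
            spacing_um=(self.SPACING_UM, self.SPACING_UM),
            origin_mm=(-half, -half),
        )

    @property
    def extent_mm(self) -> float:
        return self.SIZE * self.SPACING_UM / 1000.0
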