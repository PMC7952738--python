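"""2D rigid and affine transforms acting on en-face physical coordinates.

All transforms act on points expressed in millimetres in an en-face plane
with +x toward the nasal side (after laterality mirroring) and +y superior.
Translations are stored in micrometres to match device conventions; the
``apply`` methods take and return millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform2D", "AffineTransform2D"]

_UM_PER_MM = 1000.0


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform2D:
    """Rigid map ``p' = R(rotation) @ M @ p + t``.

    ``M`` is an x-axis mirror (``diag(-1, 1)``) applied before the rotation
    when ``mirror`` is set; it is used to bring right eyes into the
    left-eye (nasal = +x) orientation.

    Parameters
    ----------
    rotation:
        Counter-clockwise rotation in degrees.
    translation_um:
        Translation ``(tx, ty)`` in micrometres, applied after rotation.
    mirror:
        Whether to flip the x axis before rotating.
    """

    rotation: float = 0.0
    translation_um: tuple[float, float] = (0.0, 0.0)
    mirror: bool = False

    @property
    def matrix(self) -> np.ndarray:
        """Linear part (rotation composed with optional mirror)."""
        m = _rotation_matrix(self.rotation)
        if self.mirror:
            m = m @ np.diag([-1.0, 1.0])
        return m

    @property
    def translation_mm(self) -> np.ndarray:
        return np.asarray(self.translation_um) / _UM_PER_MM

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Map points, shape (..., 2), in mm."""
        p = np.asarray(points_mm, dtype=float)
        return p @ self.matrix.T + self.translation_mm

    def inverse(self) -> "AffineTransform2D":
        m = np.linalg.inv(self.matrix)
        t = -m @ self.translation_mm
        return AffineTransform2D(linear=m, translation_um=tuple(t * _UM_PER_MM))

    def as_affine(self) -> "AffineTransform2D":
        return AffineTransform2D(
            linear=self.matrix, translation_um=tuple(self.translation_um)
        )

    @staticmethod
    def identity() -> "RigidTransform2D":
        return RigidTransform2D()


@dataclass(frozen=True)
class AffineTransform2D:
    """Affine map ``p' = A @ p + t`` with ``A`` dimensionless and t in µm."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float))
        if self.linear.shape != (2, 2):
            raise ValueError("linear part must be a 2x2 matrix")

    @property
    def translation_mm(self) -> np.ndarray:
        return np.asarray(self.translation_um) / _UM_PER_MM

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.asarray(points_mm, dtype=float)
        return p @ self.linear.T + self.translation_mm

    def inverse(self) -> "AffineTransform2D":
        m = np.linalg.inv(self.linear)
        t = -m @ self.translation_mm
        return AffineTransform2D(linear=m, translation_um=tuple(t * _UM_PER_MM))

    def compose(self, inner: "AffineTransform2D | RigidTransform2D") -> "AffineTransform2D":
        """Return ``self ∘ inner`` (apply ``inner`` first)."""
        if isinstance(inner, RigidTransform2D):
            inner = inner.as_affine()
        m = self.linear @ inner.linear
        t = self.linear @ inner.translation_mm + self.translation_mm
        return AffineTransform2D(linear=m, translation_um=tuple(t * _UM_PER_MM))

    @staticmethod
    def identity() -> "AffineTransform2D":
        return AffineTransform2D()
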