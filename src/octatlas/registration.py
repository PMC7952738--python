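"""Intra-patient registration of en-face vessel maps.

All follow-up visits of one eye are aligned to its first acquisition: a
rigid stage on the binary vessel maps (mean-squares metric, robust
capture range) followed by an affine refinement on the vessel probability
maps (windowed normalized cross-correlation, window 9 px).  Both stages
run coarse-to-fine over a four-level Gaussian pyramid with a
derivative-free coordinate-descent optimizer whose steps shrink by
halving, so results are fully deterministic.

A volume-level axial de-jitter is included to remove B-scan-to-B-scan
axial offsets before any en-face projection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import AffineTransform2D, RigidTransform2D
from .types import EnfaceMap, GridSpec, OctVolume

__all__ = [
    "RegistrationResult",
    "dejitter_axial",
    "apply_transform",
    "windowed_ncc",
    "mse_similarity",
    "register_rigid",
    "register_affine",
    "register_series",
]


@dataclass
class RegistrationResult:
    transform: object  # RigidTransform2D or AffineTransform2D
    success: bool
    similarity: float
    similarity_init: float
    metric: str


# --------------------------------------------------------------------------
# axial de-jitter
# --------------------------------------------------------------------------

def dejitter_axial(volume: OctVolume, max_shift: int = 20) -> tuple[OctVolume, np.ndarray]:
    """Remove per-B-scan axial jitter by neighbor cross-correlation.

    Each B-scan's mean depth profile is aligned to its predecessor's by
    the integer shift (bounded by ``max_shift`` samples) maximizing their
    cross-correlation; cumulative shifts are median-centred so the volume
    as a whole does not drift.  Returns the corrected volume and the
    applied shifts.
    """
    if volume.n_bscan < 2:
        raise ValueError("need at least 2 B-scans")
    profiles = volume.intensities.mean(axis=1)  # (n_bscan, n_depth)
    rel = np.zeros(volume.n_bscan, dtype=int)
    for i in range(1, volume.n_bscan):
        rel[i] = _best_shift(profiles[i], profiles[i - 1], max_shift)
    cum = np.cumsum(rel)
    cum = cum - int(np.median(cum))
    cum = np.clip(cum, -max_shift, max_shift)
    out = np.empty_like(volume.intensities)
    for i, s in enumerate(cum):
        out[i] = _axial_roll(volume.intensities[i], -s)
    corrected = replace(volume, intensities=out)
    return corrected, cum


def _best_shift(profile: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    p = profile - profile.mean()
    r = ref - ref.mean()
    best, best_s = -np.inf, 0
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            a, b = p[s:], r[: len(r) - s]
        else:
            a, b = p[:s], r[-s:]
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        score = (a * b).sum() / denom if denom > 0 else 0.0
        if score > best:
            best, best_s = score, s
    return best_s


def _axial_roll(bscan: np.ndarray, shift: int) -> np.ndarray:
    out = np.zeros_like(bscan)
    if shift == 0:
        return bscan.copy()
    if shift > 0:
        out[:, shift:] = bscan[:, :-shift]
    else:
        out[:, :shift] = bscan[:, -shift:]
    return out


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def apply_transform(
    enface: EnfaceMap,
    transform: AffineTransform2D | RigidTransform2D,
    target_grid: GridSpec | None = None,
) -> EnfaceMap:
    """Resample a map through a transform onto a target grid.

    ``transform`` maps points of the map's own (moving) frame into the
    target frame; values are sampled with bilinear interpolation, the
    valid mask with nearest-neighbour, AND-ed with the in-bounds mask.
    """
    if isinstance(transform, RigidTransform2D):
        transform = transform.as_affine()
    if target_grid is None:
        target_grid = enface.grid
    inv = transform.inverse()
    tx, ty = target_grid.coordinate_arrays()
    src = inv.apply(np.stack([tx, ty], axis=-1))
    cols, rows = enface.grid.mm_to_pixel(src)
    coords = np.stack([rows, cols])
    h, w = enface.values.shape
    inb = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    filled = np.where(enface.valid_mask, enface.values, 0.0)
    vals = ndimage.map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
    # a target pixel is valid only when every bilinear neighbour is valid,
    # otherwise zero-filled invalid values would bleed across the border
    mfrac = ndimage.map_coordinates(
        enface.valid_mask.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    mask = (mfrac >= 1.0 - 1e-9) & inb
    vals = np.where(mask, vals, np.nan)
    return EnfaceMap(
        values=vals,
        spacing_um=target_grid.spacing_um,
        origin_mm=target_grid.origin_mm,
        valid_mask=mask,
        units=enface.units,
        eye_id=enface.eye_id,
        visit_id=enface.visit_id,
        group=enface.group,
        month=enface.month,
    )


# --------------------------------------------------------------------------
# similarity metrics
# --------------------------------------------------------------------------

def windowed_ncc(fixed: np.ndarray, moving: np.ndarray, mask: np.ndarray, window: int = 9) -> float:
    """Mean local normalized cross-correlation over a square window."""
    m = mask.astype(float)
    n = ndimage.uniform_filter(m, window)
    eps = 1e-12
    f = np.where(mask, fixed, 0.0)
    g = np.where(mask, moving, 0.0)
    mf = ndimage.uniform_filter(f, window) / np.maximum(n, eps)
    mg = ndimage.uniform_filter(g, window) / np.maximum(n, eps)
    cov = ndimage.uniform_filter(f * g, window) / np.maximum(n, eps) - mf * mg
    vf = ndimage.uniform_filter(f * f, window) / np.maximum(n, eps) - mf**2
    vg = ndimage.uniform_filter(g * g, window) / np.maximum(n, eps) - mg**2
    good = mask & (n > 0.5) & (vf > 1e-10) & (vg > 1e-10)
    if not good.any():
        return -np.inf
    ncc = cov[good] / np.sqrt(vf[good] * vg[good])
    return float(np.clip(ncc, -1, 1).mean())


def mse_similarity(fixed: np.ndarray, moving: np.ndarray, mask: np.ndarray) -> float:
    """Negative mean squared error (higher is better)."""
    if not mask.any():
        return -np.inf
    d = fixed[mask] - moving[mask]
    return float(-(d**2).mean())


def _similarity(fixed: EnfaceMap, moving: EnfaceMap, transform, metric: str) -> float:
    warped = apply_transform(moving, transform, fixed.grid)
    mask = fixed.valid_mask & warped.valid_mask
    if mask.mean() < 0.05:
        return -np.inf
    if metric == "NCC":
        return windowed_ncc(fixed.values, np.nan_to_num(warped.values), mask)
    if metric == "MSE":
        return mse_similarity(fixed.values, np.nan_to_num(warped.values), mask)
    raise ValueError(f"unknown metric {metric!r}")


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

def _structureless(enface: EnfaceMap) -> bool:
    """True when a map carries no usable gradient (constant or empty)."""
    if not enface.valid_mask.any():
        return True
    return float(np.nanstd(enface.values[enface.valid_mask])) < 1e-12


def _coordinate_descent(fun, x0, steps, min_steps, bounds, max_evals=4000):
    """Maximize fun by per-coordinate line moves with step halving."""
    x = np.asarray(x0, dtype=float)
    steps = np.asarray(steps, dtype=float)
    min_steps = np.asarray(min_steps, dtype=float)
    best = fun(x)
    evals = 1
    while np.any(steps > min_steps) and evals < max_evals:
        improved = False
        for i in range(len(x)):
            for sign in (+1.0, -1.0):
                while evals < max_evals:
                    cand = x.copy()
                    cand[i] += sign * steps[i]
                    if bounds is not None:
                        lo, hi = bounds[i]
                        if not (lo <= cand[i] <= hi):
                            break
                    val = fun(cand)
                    evals += 1
                    if val > best:
                        best, x = val, cand
                        improved = True
                    else:
                        break
        if not improved:
            steps = np.maximum(steps / 2.0, min_steps * 0.5)
    return x, best, evals


def _pyramid(enface: EnfaceMap, levels: int) -> list[EnfaceMap]:
    """Gaussian pyramid, coarse first; spacing doubles per level."""
    out = [enface]
    cur = enface
    for _ in range(levels - 1):
        v = np.where(cur.valid_mask, cur.values, np.nanmedian(cur.values[cur.valid_mask]))
        sm = ndimage.gaussian_filter(v, sigma=1.0)
        vals = sm[::2, ::2]
        mask = cur.valid_mask[::2, ::2]
        cur = EnfaceMap(
            values=np.where(mask, vals, np.nan),
            spacing_um=(cur.spacing_um[0] * 2, cur.spacing_um[1] * 2),
            origin_mm=cur.origin_mm,
            valid_mask=mask,
            units=cur.units,
        )
        out.append(cur)
    return out[::-1]


def register_rigid(
    moving: EnfaceMap,
    fixed: EnfaceMap,
    metric: str = "MSE",
    levels: int = 4,
    max_rotation_deg: float = 10.0,
    max_translation_um: float = 1000.0,
) -> RegistrationResult:
    """Estimate the rigid transform mapping ``moving`` into ``fixed``.

    Coarse-to-fine over a Gaussian pyramid; rotation is bounded to
    ±``max_rotation_deg`` and translation to ±``max_translation_um``
    (same-eye follow-ups).  If no parameter set beats the identity the
    identity is returned with ``success=False``.
    """
    if _structureless(fixed) or _structureless(moving):
        s = _similarity(fixed, moving, RigidTransform2D.identity(), metric)
        return RegistrationResult(RigidTransform2D.identity(), False, s, s, metric)
    fix_pyr = _pyramid(fixed, levels)
    mov_pyr = _pyramid(moving, levels)
    x = np.zeros(3)  # rot_deg, tx_um, ty_um
    bounds = [
        (-max_rotation_deg, max_rotation_deg),
        (-max_translation_um, max_translation_um),
        (-max_translation_um, max_translation_um),
    ]
    for lvl, (f, m) in enumerate(zip(fix_pyr, mov_pyr)):
        px = min(f.spacing_um)

        def fun(p, f=f, m=m):
            t = RigidTransform2D(rotation=p[0], translation_um=(p[1], p[2]))
            return _similarity(f, m, t, metric)

        steps = np.array([2.0, 4.0 * px, 4.0 * px])
        fine = lvl == len(fix_pyr) - 1
        min_steps = np.array([0.02, 0.1 * px, 0.1 * px]) if fine else np.array(
            [0.1, 0.5 * px, 0.5 * px]
        )
        x, _, _ = _coordinate_descent(fun, x, steps, min_steps, bounds)

    sol = RigidTransform2D(rotation=x[0], translation_um=(x[1], x[2]))
    s_id = _similarity(fixed, moving, RigidTransform2D.identity(), metric)
    s_sol = _similarity(fixed, moving, sol, metric)
    if not np.isfinite(s_sol) or s_sol < s_id:
        return RegistrationResult(RigidTransform2D.identity(), False, s_id, s_id, metric)
    return RegistrationResult(sol, True, s_sol, s_id, metric)


def register_affine(
    moving: EnfaceMap,
    fixed: EnfaceMap,
    init: RigidTransform2D | AffineTransform2D | None = None,
    metric: str = "NCC",
    levels: int = 4,
) -> RegistrationResult:
    """Affine refinement of a rigid initialization (NCC window 9 default).

    The admissible linear part is bounded to determinants in [0.5, 2.0].
    On failure (no improvement over ``init``) the init is returned
    embedded as an affine with ``success=False``.
    """
    if init is None:
        init = RigidTransform2D.identity()
    if isinstance(init, RigidTransform2D):
        init = init.as_affine()
    if _structureless(fixed) or _structureless(moving):
        s = _similarity(fixed, moving, init, metric)
        return RegistrationResult(init, False, s, s, metric)
    fix_pyr = _pyramid(fixed, levels)
    mov_pyr = _pyramid(moving, levels)
    x = np.array(
        [
            init.linear[0, 0],
            init.linear[0, 1],
            init.linear[1, 0],
            init.linear[1, 1],
            init.translation_um[0],
            init.translation_um[1],
        ]
    )

    def make_transform(p) -> AffineTransform2D:
        return AffineTransform2D(
            linear=np.array([[p[0], p[1]], [p[2], p[3]]]),
            translation_um=(p[4], p[5]),
        )

    for lvl, (f, m) in enumerate(zip(fix_pyr, mov_pyr)):
        px = min(f.spacing_um)

        def fun(p, f=f, m=m):
            t = make_transform(p)
            det = np.linalg.det(t.linear)
            if not 0.5 <= det <= 2.0:
                return -np.inf
            return _similarity(f, m, t, metric)

        steps = np.array([0.02, 0.02, 0.02, 0.02, 2.0 * px, 2.0 * px])
        fine = lvl == len(fix_pyr) - 1
        min_steps = (
            np.array([2e-4, 2e-4, 2e-4, 2e-4, 0.1 * px, 0.1 * px])
            if fine
            else np.array([2e-3, 2e-3, 2e-3, 2e-3, 0.5 * px, 0.5 * px])
        )
        x, _, _ = _coordinate_descent(fun, x, steps, min_steps, bounds=None)

    sol = make_transform(x)
    s_init = _similarity(fixed, moving, init, metric)
    s_sol = _similarity(fixed, moving, sol, metric)
    if not np.isfinite(s_sol) or s_sol < s_init:
        return RegistrationResult(init, False, s_init, s_init, metric)
    return RegistrationResult(sol, True, s_sol, s_init, metric)


def register_series(
    series: list[tuple[EnfaceMap, EnfaceMap]],
    rigid_metric: str = "MSE",
    affine_metric: str = "NCC",
    levels: int = 4,
    min_ncc: float = 0.2,
) -> list[RegistrationResult]:
    """Register every visit's vessel maps to the first visit.

    ``series`` is a list of (probability map, binary map) pairs, one per
    visit in temporal order.  The rigid stage runs on the binary maps
    (mean-squares), the affine refinement on the probability maps (NCC).
    Per-visit failures — optimizer divergence or a final NCC below
    ``min_ncc`` (no real correspondence, e.g. an unusable acquisition) —
    are flagged rather than raised so failed visits can be excluded
    downstream.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    ref_prob, ref_bin = series[0]
    results = [
        RegistrationResult(AffineTransform2D.identity(), True, 1.0, 1.0, affine_metric)
    ]
    for prob, binary in series[1:]:
        rigid = register_rigid(binary, ref_bin, metric=rigid_metric, levels=levels)
        affine = register_affine(
            prob, ref_prob, init=rigid.transform, metric=affine_metric, levels=levels
        )
        success = rigid.success and affine.success
        if affine_metric == "NCC" and affine.similarity < min_ncc:
            success = False
        results.append(replace(affine, success=success))
    return results
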