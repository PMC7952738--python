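"""Synthetic OCT phantom eyes and longitudinal cohorts with known truth.

Every downstream stage of the atlas pipeline (projection, registration,
landmark detection, normalization, feature mapping, population statistics,
joint modelling) is exercised against phantoms produced here, because the
clinical cohort the method was developed on is not publicly available.

A phantom eye consists of

* smooth per-layer thickness fields over the en-face plane with a foveal
  pit (inner layers thin out toward the fovea),
* a vessel tree rooted at the optic nerve head that casts shadows through
  the outer retina — the physical effect the vessel-map recipe exploits,
* per-visit rigid misalignments (visit 0 defines the eye's own frame),
* group-specific linear trajectories of the central-area features, with
  per-eye random intercepts and slopes, and
* a conversion time drawn from a piecewise-constant proportional-hazards
  model whose log-hazard is linear in the eye's random effects.

Default trajectory coefficients are the growth-curve estimates for the
three clinical groups (non-progressors, MNV converters, MA converters);
see :class:`CohortConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import RigidTransform2D
from .types import GridSpec, LayerSurfaces, OctVolume, SloImage, SURFACE_ORDER

__all__ = [
    "GROUPS",
    "FEATURES",
    "HazardParams",
    "CohortConfig",
    "EyePhantom",
    "generate_eye_phantom",
    "render_visit",
    "render_surfaces",
    "render_enface_reflectance",
    "vessel_shadow_attenuation",
    "simulate_cohort",
]

GROUPS = ("MNV", "MA", "NONP")
FEATURES = ("ONL", "ORB", "CHOROID", "CSHADE")

# Phantom acquisition geometry: 200 A-scans x 128 B-scans x 320 depth
# samples at (ascan 30, bscan 60, depth 3.9) µm -- anisotropic like a
# clinical macular cube.
N_ASCAN = 200
N_BSCAN = 128
N_DEPTH = 320
ASCAN_UM = 30.0
BSCAN_UM = 60.0
DEPTH_UM = 3.9
BM_DEPTH_UM = 800.0
N_VISITS = 25  # monthly, months 0..24

_LAYER_INTENSITY = {
    "vitreous": 12.0,
    "RNFL": 185.0,
    "GCL_IPL": 120.0,
    "INL_OPL": 110.0,
    "ONL": 60.0,
    "ORB": 225.0,
    "CHOROID": 90.0,
    "sclera": 30.0,
}


@dataclass
class HazardParams:
    """Piecewise-constant baseline hazard with shared-random-effect link.

    The hazard of eye *i* at month *t* in interval *k* is
    ``rate_k * multiplier[group] * exp(a0*b0_i + a1*b1_i)`` where
    ``(b0_i, b1_i)`` are the random intercept/slope of ``link_feature``.
    Non-progressors have multiplier 0 by definition of their label.
    """

    breakpoints: tuple = (0.0, 6.0, 12.0, 18.0, 24.0)
    baseline_rates: tuple = (0.08, 0.08, 0.08, 0.08)
    group_multiplier: dict = field(
        default_factory=lambda: {"MNV": 1.0, "MA": 1.0, "NONP": 0.0}
    )
    association: tuple = (-0.02, -2.0)
    link_feature: str = "ONL"

    def __post_init__(self):
        if len(self.baseline_rates) != len(self.breakpoints) - 1:
            raise ValueError("need one rate per interval")
        if any(r < 0 for r in self.baseline_rates):
            raise ValueError("rates must be non-negative")

    def eye_rates(self, group: str, b: tuple[float, float]) -> np.ndarray:
        scale = self.group_multiplier[group] * math.exp(
            self.association[0] * b[0] + self.association[1] * b[1]
        )
        return np.asarray(self.baseline_rates) * scale

    def sample_event_time(self, group: str, b, rng: np.random.Generator) -> float | None:
        """Inverse-transform sample; None when no event before the last break."""
        rates = self.eye_rates(group, b)
        target = rng.exponential(1.0)  # -log U
        acc = 0.0
        for k, rate in enumerate(rates):
            dt = self.breakpoints[k + 1] - self.breakpoints[k]
            if acc + rate * dt >= target:
                if rate == 0:
                    return None
                return self.breakpoints[k] + (target - acc) / rate
            acc += rate * dt
        return None


def _table_defaults():
    baselines = {"ONL": 90.78, "ORB": 60.68, "CHOROID": 132.19, "CSHADE": 69.06}
    offsets = {
        "ONL": {"MNV": -3.1, "MA": -9.15},
        "ORB": {"MNV": 0.31, "MA": -1.15},
        "CHOROID": {"MNV": 4.84, "MA": -3.31},
        "CSHADE": {"MNV": -7.82, "MA": -9.65},
    }
    slopes = {"ONL": -0.11, "ORB": -0.023, "CHOROID": -0.47, "CSHADE": -0.24}
    slope_offsets = {
        "ONL": {"MNV": -0.080, "MA": -0.11},
        "ORB": {"MNV": -0.094, "MA": -0.12},
        "CHOROID": {"MNV": -0.38, "MA": -0.20},
        "CSHADE": {"MNV": 0.086, "MA": 0.16},
    }
    return baselines, offsets, slopes, slope_offsets


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Trajectory defaults are the published growth-curve coefficients per
    feature (µm, µm/month; texture in its own units); group sizes default
    to the clinical cohort (135 MNV / 50 MA / 333 non-progressors).
    Random-effect and residual scales are not published; defaults are
    plausible clinical magnitudes chosen once (see the methods note).
    """

    n_per_group: dict = field(
        default_factory=lambda: {"MNV": 135, "MA": 50, "NONP": 333}
    )
    baseline_means: dict = field(default_factory=lambda: _table_defaults()[0])
    group_offsets: dict = field(default_factory=lambda: _table_defaults()[1])
    slopes: dict = field(default_factory=lambda: _table_defaults()[2])
    slope_offsets: dict = field(default_factory=lambda: _table_defaults()[3])
    random_effect_sd: dict = field(
        default_factory=lambda: {
            "ONL": (7.5, 0.08),
            "ORB": (3.0, 0.04),
            "CHOROID": (30.0, 0.30),
            "CSHADE": (15.0, 0.20),
        }
    )
    residual_sd: dict = field(
        default_factory=lambda: {"ONL": 2.0, "ORB": 1.0, "CHOROID": 5.0, "CSHADE": 5.0}
    )
    hazard_params: HazardParams = field(default_factory=HazardParams)
    n_visits: int = N_VISITS
    drusen: bool = False
    #: restrict the ONL group offset to an eccentricity annulus (mm), for
    #: experiments with spatially localized thinning; None = global offset
    onl_offset_annulus_mm: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if n < 1:
                raise ValueError("n_per_group must be >= 1")
        for f, (s0, s1) in self.random_effect_sd.items():
            if s0 < 0 or s1 < 0:
                raise ValueError("random-effect sds must be >= 0")
        if any(s < 0 for s in self.residual_sd.values()):
            raise ValueError("residual sds must be >= 0")

    def trajectory_mean(self, feature: str, group: str, month) -> np.ndarray:
        """Population-mean feature value (no random effects)."""
        base = self.baseline_means[feature]
        slope = self.slopes[feature]
        if group != "NONP":
            base += self.group_offsets[feature][group]
            slope += self.slope_offsets[feature][group]
        return base + slope * np.asarray(month)


@dataclass
class EyePhantom:
    """One synthetic eye with known geometry, trajectories and fate."""

    eye_id: str
    laterality: str
    group: str
    config: CohortConfig
    fovea_true: np.ndarray
    onh_center_true: np.ndarray
    onh_radius_true: float
    vessel_tree: list  # [(polyline (N,2) mm, width_um, attenuation), ...]
    random_effects: dict  # feature -> (b0, b1)
    conversion_time: float | None
    per_visit_transforms: list

    def __post_init__(self):
        if self.conversion_time is not None and self.conversion_time <= 0:
            raise ValueError("conversion_time must be positive")

    @property
    def censored(self) -> bool:
        return self.conversion_time is None

    def feature_mean(self, feature: str, month: float) -> float:
        """Central-3-mm mean of a feature at a given month (noise-free)."""
        b0, b1 = self.random_effects[feature]
        return float(self.config.trajectory_mean(feature, self.group, month) + b0 + b1 * month)

    # ---- geometry ------------------------------------------------------
    def _radius(self, x, y):
        return np.hypot(x - self.fovea_true[0], y - self.fovea_true[1])

    def layer_thickness(self, layer: str, x, y, month: float = 0.0) -> np.ndarray:
        """Thickness field in µm over en-face eye coordinates (mm)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r = self._radius(x, y)
        if layer == "RNFL":
            t = 4.0 + 26.0 * np.clip(r / 3.0, 0.0, 1.3) ** 1.5
        elif layer == "GCL_IPL":
            t = 12.0 + 65.0 * np.exp(-(((r - 1.1) / 0.7) ** 2))
        elif layer == "INL_OPL":
            t = 15.0 + 45.0 * np.exp(-(((r - 1.3) / 0.9) ** 2))
        elif layer == "ONL":
            t = np.full_like(r, self.feature_mean("ONL", month))
            ann = self.config.onl_offset_annulus_mm
            if ann is not None and self.group != "NONP":
                # move the group offset out of the global mean and into
                # the annulus only
                off = self.config.group_offsets["ONL"][self.group]
                t = t - off + off * _annulus_weight(r, *ann)
        elif layer == "ORB":
            t = np.full_like(r, self.feature_mean("ORB", month))
        elif layer == "CHOROID":
            t = np.full_like(r, self.feature_mean("CHOROID", month))
        else:
            raise KeyError(f"unknown layer {layer!r}")
        return np.maximum(t, 1.0)

    def surface_depths(self, x, y, month: float = 0.0) -> dict:
        """Boundary depth maps (µm from volume top) at eye coordinates."""
        retina = ["RNFL", "GCL_IPL", "INL_OPL", "ONL", "ORB"]
        th = {l: self.layer_thickness(l, x, y, month) for l in retina + ["CHOROID"]}
        total = sum(th[l] for l in retina)
        ilm = BM_DEPTH_UM - total
        out = {"ILM": ilm}
        depth = ilm
        for name, layer in zip(SURFACE_ORDER[1:6], retina):
            depth = depth + th[layer]
            out[name] = depth
        out["CHOROID_POST"] = out["BM"] + th["CHOROID"]
        if self.config.drusen:
            _add_drusen(out, x, y, self.eye_id)
        return out


def _annulus_weight(r, r0, r1, soft=0.1):
    """Smooth indicator of r in [r0, r1] with `soft` mm cosine flanks."""
    lo = np.clip((r - (r0 - soft)) / soft, 0.0, 1.0)
    hi = np.clip(((r1 + soft) - r) / soft, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * lo)) * 0.5 * (1 - np.cos(np.pi * hi))


def _add_drusen(surfaces: dict, x, y, eye_id: str):
    """Hemispherical RPE elevations: lift the inner ORB boundary."""
    rng = np.random.default_rng(abs(hash(("drusen", eye_id))) % (2**31))
    for _ in range(10):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.5, 2.5)
        cx, cy = rad * np.cos(ang), rad * np.sin(ang)
        R = rng.uniform(0.15, 0.4)
        amp = rng.uniform(20.0, 80.0)
        d2 = ((np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2) / R**2
        bump = amp * np.sqrt(np.clip(1.0 - d2, 0.0, None))
        surfaces["ONL_ORB"] = np.maximum(
            surfaces["ONL_ORB"] - bump, surfaces["OPL_ONL"] + 2.0
        )


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------

def _make_vessel_tree(onh: np.ndarray, fovea: np.ndarray, rng: np.random.Generator):
    """Branches fanning from the ONH across the macula, as 2D polylines."""
    psi = math.atan2(fovea[1] - onh[1], fovea[0] - onh[0])
    tree = []
    n_branch = 8
    spread = np.linspace(-1.35, 1.35, n_branch) + rng.normal(0, 0.06, n_branch)
    for k in range(n_branch):
        theta = psi + spread[k]
        kappa = rng.normal(0.0, 0.02) - 0.03 * np.sign(spread[k])
        pts = [onh.copy()]
        p = onh.copy()
        step = 0.25
        for _ in range(44):
            p = p + step * np.array([math.cos(theta), math.sin(theta)])
            theta += kappa
            pts.append(p.copy())
        width = rng.uniform(70.0, 140.0)
        atten = rng.uniform(0.4, 0.7)
        tree.append((np.asarray(pts), width, atten))
    return tree


def generate_eye_phantom(
    config: CohortConfig, group: str, seed: int
) -> EyePhantom:
    """Create one phantom eye of the given group.

    The central-3-mm mean ONL thickness at month ``t`` equals
    ``baseline + group offset + slope*t + b0 + b1*t`` by construction.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(seed)
    laterality = "OD" if rng.random() < 0.5 else "OS"
    fovea = rng.normal(0.0, 0.15, size=2).clip(-0.4, 0.4)
    # ONH sits nasally ~4.2 mm from the fovea, slightly superior; in the
    # acquisition frame of a right eye nasal is -x (mirrored later).
    dist = rng.normal(4.2, 0.15)
    ang = math.radians(rng.normal(5.6, 1.5))
    direction = 1.0 if laterality == "OS" else -1.0
    onh = fovea + np.array([direction * dist * math.cos(ang), dist * math.sin(ang)])
    onh_radius = float(np.clip(rng.normal(0.9, 0.08), 0.6, 1.2))
    tree = _make_vessel_tree(onh, fovea, rng)

    b = {
        f: (
            rng.normal(0.0, config.random_effect_sd[f][0]),
            rng.normal(0.0, config.random_effect_sd[f][1]),
        )
        for f in FEATURES
    }
    link = config.hazard_params.link_feature
    conv = config.hazard_params.sample_event_time(group, b[link], rng)
    if conv is not None and conv > config.n_visits - 1:
        conv = None  # administratively censored at the end of follow-up

    transforms = [RigidTransform2D.identity()]
    for _ in range(1, config.n_visits):
        rot = float(np.clip(rng.normal(0.0, 1.5), -4.0, 4.0))
        t = np.clip(rng.normal(0.0, 120.0, size=2), -280.0, 280.0)
        transforms.append(RigidTransform2D(rotation=rot, translation_um=tuple(t)))

    return EyePhantom(
        eye_id=f"{group}-{seed}",
        laterality=laterality,
        group=group,
        config=config,
        fovea_true=np.asarray(fovea, dtype=float),
        onh_center_true=np.asarray(onh, dtype=float),
        onh_radius_true=onh_radius,
        vessel_tree=tree,
        random_effects=b,
        conversion_time=conv,
        per_visit_transforms=transforms,
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _default_enface_grid() -> GridSpec:
    origin = (-(N_ASCAN - 1) * ASCAN_UM / 2000.0, -(N_BSCAN - 1) * BSCAN_UM / 2000.0)
    return GridSpec(shape=(N_BSCAN, N_ASCAN), spacing_um=(ASCAN_UM, BSCAN_UM), origin_mm=origin)


def vessel_shadow_attenuation(
    phantom: EyePhantom, x_mm: np.ndarray, y_mm: np.ndarray
) -> np.ndarray:
    """Fractional intensity attenuation under the vessel tree, in [0, 1).

    Each branch contributes a Gaussian lateral profile (sigma = width/2)
    of its own peak attenuation; branches combine as independent filters.
    """
    transmission = np.ones_like(np.asarray(x_mm, dtype=float))
    pts = np.stack([np.asarray(x_mm), np.asarray(y_mm)], axis=-1)
    for poly, width_um, atten in phantom.vessel_tree:
        d = _dist_to_polyline(pts, poly)
        sigma = width_um / 2000.0  # mm
        transmission *= 1.0 - atten * np.exp(-0.5 * (d / sigma) ** 2)
    return 1.0 - transmission


def _dist_to_polyline(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point (..., 2) to a polyline (N, 2), in mm."""
    p = pts[..., None, :]  # (..., 1, 2)
    a = poly[:-1]  # (S, 2)
    ab = poly[1:] - a  # (S, 2)
    denom = np.maximum((ab**2).sum(-1), 1e-12)
    t = np.clip(((p - a) * ab).sum(-1) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    d = np.sqrt(((p - proj) ** 2).sum(-1))
    return d.min(axis=-1)


def render_surfaces(phantom: EyePhantom, visit_index: int) -> LayerSurfaces:
    """Ground-truth boundary surfaces of one visit, without the volume.

    Same contract as the surfaces returned by :func:`render_visit`
    (misaligned by the visit's transform, noise-free), but skips the
    3D intensity rendering — used when only thickness maps are needed.
    """
    if not 0 <= visit_index < phantom.config.n_visits:
        raise ValueError(
            f"visit {visit_index} outside the monthly schedule "
            f"(0..{phantom.config.n_visits - 1})"
        )
    T = phantom.per_visit_transforms[visit_index]
    grid = _default_enface_grid()
    gx, gy = grid.coordinate_arrays()
    eye_pts = T.apply(np.stack([gx, gy], axis=-1))
    sd = phantom.surface_depths(eye_pts[..., 0], eye_pts[..., 1], float(visit_index))
    return LayerSurfaces(surfaces=sd, spacing_um=(BSCAN_UM, ASCAN_UM), origin_mm=grid.origin_mm)


def render_visit(
    phantom: EyePhantom,
    visit_index: int,
    noise_sd: float = 4.0,
    seed: int = 0,
) -> tuple[OctVolume, SloImage, LayerSurfaces]:
    """Render one visit: OCT volume, SLO image and ground-truth surfaces.

    The acquisition is misaligned by the visit's ground-truth rigid
    transform; the returned surfaces are the noise-free truth in the
    acquisition frame.  ``noise_sd = 0`` renders a fully deterministic
    volume (no speckle either).
    """
    if not 0 <= visit_index < phantom.config.n_visits:
        raise ValueError(
            f"visit {visit_index} outside the monthly schedule "
            f"(0..{phantom.config.n_visits - 1})"
        )
    month = float(visit_index)
    T = phantom.per_visit_transforms[visit_index]
    grid = _default_enface_grid()
    gx, gy = grid.coordinate_arrays()
    eye_pts = T.apply(np.stack([gx, gy], axis=-1))
    ex, ey = eye_pts[..., 0], eye_pts[..., 1]

    sd = phantom.surface_depths(ex, ey, month)
    surfaces = LayerSurfaces(
        surfaces=sd,
        spacing_um=(BSCAN_UM, ASCAN_UM),
        origin_mm=grid.origin_mm,
    )

    z = (np.arange(N_DEPTH) * DEPTH_UM)[None, None, :]
    vol = np.full((N_BSCAN, N_ASCAN, N_DEPTH), _LAYER_INTENSITY["vitreous"], dtype=np.float32)
    bands = [
        ("RNFL", "ILM", "RNFL_GCL"),
        ("GCL_IPL", "RNFL_GCL", "IPL_INL"),
        ("INL_OPL", "IPL_INL", "OPL_ONL"),
        ("ONL", "OPL_ONL", "ONL_ORB"),
        ("ORB", "ONL_ORB", "BM"),
        ("CHOROID", "BM", "CHOROID_POST"),
    ]
    for layer, top, bot in bands:
        sel = (z >= sd[top][..., None]) & (z < sd[bot][..., None])
        vol[sel] = _LAYER_INTENSITY[layer]
    below = z >= sd["CHOROID_POST"][..., None]
    vol[below] = _LAYER_INTENSITY["sclera"]

    atten = vessel_shadow_attenuation(phantom, ex, ey)
    shadow_band = (z >= (sd["ILM"] + 10.0)[..., None]) & (z < sd["BM"][..., None])
    vol = np.where(shadow_band, vol * (1.0 - atten[..., None]), vol)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        speckle = rng.gamma(25.0, 1.0 / 25.0, size=vol.shape).astype(np.float32)
        vol = vol * speckle + rng.normal(0.0, noise_sd, size=vol.shape).astype(np.float32)
    vol = np.clip(vol, 0.0, 255.0).astype(np.float32)

    volume = OctVolume(
        intensities=vol,
        spacing_um=(BSCAN_UM, ASCAN_UM, DEPTH_UM),
        laterality=phantom.laterality,
        eye_id=phantom.eye_id,
        visit_id=f"v{visit_index:02d}",
        month=month,
        origin_mm=grid.origin_mm,
    )
    slo = _render_slo(phantom, T, noise_sd, seed)
    return volume, slo, surfaces


def _render_slo(phantom: EyePhantom, T: RigidTransform2D, noise_sd: float, seed: int) -> SloImage:
    """SLO fundus image: bright background, dark vessels, dark ONH disc."""
    n, spacing = 300, 30.0
    origin = (-(n - 1) * spacing / 2000.0, -(n - 1) * spacing / 2000.0)
    grid = GridSpec(shape=(n, n), spacing_um=(spacing, spacing), origin_mm=origin)
    gx, gy = grid.coordinate_arrays()
    eye_pts = T.apply(np.stack([gx, gy], axis=-1))
    ex, ey = eye_pts[..., 0], eye_pts[..., 1]
    img = np.full((n, n), 180.0)
    img *= 1.0 - 0.85 * vessel_shadow_attenuation(phantom, ex, ey)
    d_onh = np.hypot(ex - phantom.onh_center_true[0], ey - phantom.onh_center_true[1])
    disc = 1.0 / (1.0 + np.exp((d_onh - phantom.onh_radius_true) / 0.02))
    img = img * (1 - disc) + 55.0 * disc
    if noise_sd > 0:
        rng = np.random.default_rng(seed + 1)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return SloImage(values=np.clip(img, 0, 255), spacing_um=spacing, origin_mm=origin)


def render_enface_reflectance(
    phantom: EyePhantom,
    visit_index: int,
    grid: GridSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sub-RPE en-face reflectance image (bright field, dark vessel shadows).

    A fast stand-in for rendering the full volume and projecting it; used
    for registration experiments where only the en-face pattern matters.
    """
    if grid is None:
        grid = _default_enface_grid()
    T = phantom.per_visit_transforms[visit_index]
    gx, gy = grid.coordinate_arrays()
    eye_pts = T.apply(np.stack([gx, gy], axis=-1))
    img = 220.0 * (1.0 - vessel_shadow_attenuation(phantom, eye_pts[..., 0], eye_pts[..., 1]))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[EyePhantom]]:
    """Simulate a longitudinal cohort under the configured study design.

    Returns a long-format feature table (eye_id, group, month, feature,
    value), a survival table (eye_id, group, time, event) and the list of
    phantoms.  Visits are monthly; a converter contributes visits strictly
    before its conversion time, a non-converter all visits through the end
    of follow-up.
    """
    ss = np.random.SeedSequence(config.seed)
    phantoms: list[EyePhantom] = []
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        child_seeds = ss.spawn(n)
        for i, cs in enumerate(child_seeds):
            seed = int(cs.generate_state(1)[0] % (2**31))
            ph = generate_eye_phantom(config, group, seed)
            ph.eye_id = f"{group}-{i:04d}"
            phantoms.append(ph)

    rng = np.random.default_rng(ss.spawn(1)[0])
    long_rows, surv_rows = [], []
    last_month = config.n_visits - 1
    for ph in phantoms:
        if ph.conversion_time is not None:
            months = [m for m in range(config.n_visits) if m < ph.conversion_time]
            time, event = float(ph.conversion_time), True
        else:
            months = list(range(config.n_visits))
            time, event = float(last_month), False
        for f in FEATURES:
            res = config.residual_sd[f]
            noise = rng.normal(0.0, res, size=len(months)) if res > 0 else np.zeros(len(months))
            for m, e in zip(months, noise):
                long_rows.append(
                    (ph.eye_id, ph.group, float(m), f, ph.feature_mean(f, m) + e)
                )
        surv_rows.append((ph.eye_id, ph.group, time, event))

    long_df = pd.DataFrame(long_rows, columns=["eye_id", "group", "month", "feature", "value"])
    surv_df = pd.DataFrame(surv_rows, columns=["eye_id", "group", "time", "event"])
    return long_df, surv_df, phantoms
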