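"""Align a misaligned follow-up visit and map it into the atlas frame.

Registers visit 1 (with a known simulated eye-position shift) back to
visit 0, compares the recovered rigid transform with the ground truth,
then detects the fovea and ONH landmarks and resamples the ONL thickness
map into the 512x512 @ 15 µm fovea-centred reference grid.
"""

import numpy as np

import octatlas as oa
from octatlas.features import thickness_map
from octatlas.landmarks import LandmarkSet, detect_fovea_from_surfaces, detect_onh
from octatlas.longitudinal import central_mean
from octatlas.refframe import build_normalization_transform, resample_to_atlas
from octatlas.registration import register_rigid
from octatlas.synthetic import _default_enface_grid, render_enface_reflectance
from octatlas.types import EnfaceMap

config = oa.CohortConfig(n_per_group={"MA": 1}, seed=0)
phantom = oa.generate_eye_phantom(config, "MA", seed=9)
grid = _default_enface_grid()

fixed = EnfaceMap(values=render_enface_reflectance(phantom, 0),
                  spacing_um=grid.spacing_um, origin_mm=grid.origin_mm)
moving = EnfaceMap(values=render_enface_reflectance(phantom, 1),
                   spacing_um=grid.spacing_um, origin_mm=grid.origin_mm)
res = register_rigid(moving, fixed, metric="MSE")
truth = phantom.per_visit_transforms[1]
print(f"true misalignment:  {truth.rotation:+.2f} deg, {np.round(truth.translation_um, 1)} µm")
print(f"recovered:          {res.transform.rotation:+.2f} deg, "
      f"{np.round(res.transform.translation_um, 1)} µm (success={res.success})")

_, slo, surfaces = oa.render_visit(phantom, 0, noise_sd=4.0, seed=2)
fovea = detect_fovea_from_surfaces(surfaces)
onh = detect_onh(slo)
print(f"fovea detected at {np.round(fovea.position_mm, 3)} mm "
      f"(truth {np.round(phantom.fovea_true, 3)})")
print(f"ONH detected at {np.round(onh.center_mm, 3)} mm, r={onh.radius_mm:.2f} mm "
      f"(truth {np.round(phantom.onh_center_true, 3)}, r={phantom.onh_radius_true:.2f})")

landmarks = LandmarkSet(fovea=fovea.position_mm, onh_center=onh.center_mm,
                        onh_radius=onh.radius_mm)
inter = build_normalization_transform(landmarks, phantom.laterality)
onl = thickness_map(surfaces, "OPL_ONL", "ONL_ORB")
atlas_map = resample_to_atlas(onl, inter=inter)
print(f"atlas ONL map: {atlas_map.values.shape}, valid fraction "
      f"{atlas_map.valid_mask.mean():.2f}")
print(f"central-3-mm ONL mean: {central_mean(atlas_map):.2f} µm "
      f"(noise-free truth {phantom.feature_mean('ONL', 0):.2f})")
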