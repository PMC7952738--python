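"""Pixelwise group comparison and topographic profiles in atlas space.

Builds atlas-space ONL maps for a small MA-converter vs non-progressor
cohort in which the MA thinning is confined to the 0.3-2 mm annulus,
runs the pixelwise Mann-Whitney test with FDR control and summarizes
the same data as an eccentricity profile, printing where the
significant bins fall.
"""

import numpy as np

import octatlas as oa
from octatlas.features import thickness_map
from octatlas.landmarks import LandmarkSet
from octatlas.popstats import fdr_correct, group_maps, pixelwise_mwu, topographic_profile
from octatlas.refframe import build_normalization_transform, resample_to_atlas
from octatlas.synthetic import render_surfaces

config = oa.CohortConfig(
    n_per_group={"MA": 25, "NONP": 40},
    onl_offset_annulus_mm=(0.3, 2.0),
    seed=2,
)
maps = []
for group, n in (("MA", 25), ("NONP", 40)):
    for i in range(n):
        ph = oa.generate_eye_phantom(config, group, seed=100 * (i + 1) + len(group))
        surf = render_surfaces(ph, 0)
        onl = thickness_map(surf, "OPL_ONL", "ONL_ORB")
        lm = LandmarkSet(fovea=ph.fovea_true, onh_center=ph.onh_center_true,
                         onh_radius=ph.onh_radius_true)
        am = resample_to_atlas(onl, intra=ph.per_visit_transforms[0],
                               inter=build_normalization_transform(lm, ph.laterality))
        am.group = group
        maps.append(am)

res = group_maps(maps)
print("mean central ONL (µm):",
      {g: round(float(np.nanmean(res.mean[g])), 1) for g in res.mean})

diff, p = pixelwise_mwu([m for m in maps if m.group == "MA"],
                        [m for m in maps if m.group == "NONP"])
mask, _ = fdr_correct(p, alpha=0.05)
print(f"pixels significant after 5% FDR: {mask.sum()} "
      f"({100 * mask.mean():.1f}% of the atlas)")

prof = topographic_profile(maps, bin_width_mm=0.1, max_ecc_mm=3.5,
                           test_pair=("MA", "NONP"))
sig_centers = prof.bin_centers_mm[prof.significant]
if len(sig_centers):
    print(f"significant profile bins span {sig_centers.min():.2f}-"
          f"{sig_centers.max():.2f} mm eccentricity")
    print("(the thinning was simulated only between 0.3 and 2.0 mm)")
else:
    print("no significant profile bins")
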