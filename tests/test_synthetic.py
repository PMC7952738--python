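import numpy as np
import pandas as pd
import pytest

import octatlas as oa
from octatlas.synthetic import (
    FEATURES,
    HazardParams,
    vessel_shadow_attenuation,
)


def _deterministic_config(**kw):
    base = dict(
        n_per_group={"MNV": 2, "MA": 2, "NONP": 2},
        random_effect_sd={f: (0.0, 0.0) for f in FEATURES},
        residual_sd={f: 0.0 for f in FEATURES},
        seed=0,
    )
    base.update(kw)
    return oa.CohortConfig(**base)


class TestGenerateEyePhantom:
    def test_nonp_baseline_central_onl_mean(self):
        cfg = _deterministic_config()
        ph = oa.generate_eye_phantom(cfg, "NONP", seed=1)
        assert ph.feature_mean("ONL", 0.0) == pytest.approx(90.78)

    def test_ma_offset_is_deterministic_without_random_effects(self):
        cfg = _deterministic_config()
        for seed in (1, 7, 99):
            ph = oa.generate_eye_phantom(cfg, "MA", seed=seed)
            assert ph.feature_mean("ONL", 0.0) == pytest.approx(90.78 - 9.15)

    def test_trajectory_includes_slope_and_random_effects(self, small_config):
        ph = oa.generate_eye_phantom(small_config, "MNV", seed=3)
        b0, b1 = ph.random_effects["ONL"]
        expected = (90.78 - 3.1) + b0 + ((-0.11 - 0.080) + b1) * 7.0
        assert ph.feature_mean("ONL", 7.0) == pytest.approx(expected)

    def test_seeded_determinism(self, small_config):
        a = oa.generate_eye_phantom(small_config, "NONP", seed=11)
        b = oa.generate_eye_phantom(small_config, "NONP", seed=11)
        assert np.array_equal(a.fovea_true, b.fovea_true)
        assert np.array_equal(a.onh_center_true, b.onh_center_true)
        for (pa, wa, aa), (pb, wb, ab) in zip(a.vessel_tree, b.vessel_tree):
            assert np.array_equal(pa, pb) and wa == wb and aa == ab

    def test_unknown_group_rejected(self, small_config):
        with pytest.raises(ValueError, match="unknown group"):
            oa.generate_eye_phantom(small_config, "XXX", seed=0)

    def test_vessel_tree_crosses_macular_circle(self, small_config):
        """At least 5 branches cross the 6-mm-diameter circle at the fovea."""
        for seed in range(5):
            ph = oa.generate_eye_phantom(small_config, "NONP", seed=seed)
            crossing = 0
            for poly, _, _ in ph.vessel_tree:
                r = np.hypot(*(poly - ph.fovea_true).T)
                if r.min() < 3.0 < r.max():
                    crossing += 1
            assert crossing >= 5

    def test_fovea_pit_at_true_position(self, small_config, enface_grid):
        """The ILM-GCL thickness argmin coincides with fovea_true."""
        ph = oa.generate_eye_phantom(small_config, "NONP", seed=2)
        x, y = enface_grid.coordinate_arrays()
        rnfl = ph.layer_thickness("RNFL", x, y)
        iy, ix = np.unravel_index(np.argmin(rnfl), rnfl.shape)
        pos = enface_grid.pixel_to_mm(ix, iy)
        assert np.all(np.abs(pos - ph.fovea_true) <= np.array([0.03, 0.06]) + 1e-9)

    def test_thickness_fields_strictly_positive(self, small_config, enface_grid):
        ph = oa.generate_eye_phantom(small_config, "MA", seed=4)
        x, y = enface_grid.coordinate_arrays()
        for layer in ("RNFL", "GCL_IPL", "INL_OPL", "ONL", "ORB", "CHOROID"):
            assert np.all(ph.layer_thickness(layer, x, y, 24.0) > 0)


class TestRenderVisit:
    def test_visit0_surfaces_equal_ground_truth(self, phantom, clean_visit, enface_grid):
        _, _, surf = clean_visit
        x, y = enface_grid.coordinate_arrays()
        truth = phantom.surface_depths(x, y, 0.0)
        for name in truth:
            assert np.allclose(surf[name], truth[name])

    def test_volume_intensity_range_and_determinism(self, phantom):
        v1, _, _ = oa.render_visit(phantom, 1, noise_sd=4.0, seed=9)
        v2, _, _ = oa.render_visit(phantom, 1, noise_sd=4.0, seed=9)
        assert v1.intensities.min() >= 0 and v1.intensities.max() <= 255
        assert np.array_equal(v1.intensities, v2.intensities)

    def test_visit_beyond_schedule_rejected(self, phantom):
        with pytest.raises(ValueError, match="schedule"):
            oa.render_visit(phantom, 25)

    def test_vessel_shadow_darkens_projection(self, phantom, clean_visit, enface_grid):
        from octatlas.enface import percentile_projection

        vol, _, surf = clean_visit
        proj = percentile_projection(vol, surf["BM"])
        x, y = enface_grid.coordinate_arrays()
        att = vessel_shadow_attenuation(phantom, x, y)
        shadow, background = att > 0.3, att < 0.02
        assert proj.values[shadow].mean() < proj.values[background].mean() - 30

    def test_slo_shows_dark_disc_at_onh(self, phantom, clean_visit):
        _, slo, _ = clean_visit
        cols, rows = slo.grid.mm_to_pixel(phantom.onh_center_true)
        r, c = int(round(float(rows))), int(round(float(cols)))
        inside = slo.values[r, c]
        assert inside < 80
        assert slo.values.max() > 150

    def test_surfaces_misaligned_by_visit_transform(self, phantom, enface_grid):
        _, _, surf = oa.render_visit(phantom, 3, noise_sd=0.0, seed=0)
        T = phantom.per_visit_transforms[3]
        x, y = enface_grid.coordinate_arrays()
        pts = T.apply(np.stack([x, y], axis=-1))
        truth = phantom.surface_depths(pts[..., 0], pts[..., 1], 3.0)
        assert np.allclose(surf["ILM"], truth["ILM"])


class TestSimulateCohort:
    def test_zero_hazard_all_censored_25_visits(self):
        cfg = _deterministic_config(
            hazard_params=HazardParams(baseline_rates=(0.0, 0.0, 0.0, 0.0))
        )
        long_df, surv_df, _ = oa.simulate_cohort(cfg)
        assert not surv_df["event"].any()
        assert (surv_df["time"] == 24.0).all()
        per_eye = long_df[long_df.feature == "ONL"].groupby("eye_id").size()
        assert (per_eye == 25).all()

    def test_noiseless_nonp_trajectory_exact(self):
        cfg = _deterministic_config()
        long_df, _, _ = oa.simulate_cohort(cfg)
        sel = long_df[(long_df.group == "NONP") & (long_df.feature == "ONL")]
        assert np.allclose(sel["value"], 90.78 - 0.11 * sel["month"])

    def test_row_count_matches_visits_before_event(self):
        cfg = oa.CohortConfig(n_per_group={"MNV": 20, "MA": 5, "NONP": 5}, seed=3)
        long_df, surv_df, phantoms = oa.simulate_cohort(cfg)
        for ph in phantoms:
            rows = long_df[(long_df.eye_id == ph.eye_id) & (long_df.feature == "ONL")]
            if ph.conversion_time is None:
                assert len(rows) == 25
            else:
                assert len(rows) == sum(m < ph.conversion_time for m in range(25))

    def test_seeded_determinism(self):
        cfg = oa.CohortConfig(n_per_group={"MNV": 4, "MA": 2, "NONP": 4}, seed=17)
        a = oa.simulate_cohort(cfg)[0]
        b = oa.simulate_cohort(oa.CohortConfig(n_per_group={"MNV": 4, "MA": 2, "NONP": 4}, seed=17))[0]
        pd.testing.assert_frame_equal(a, b)

    def test_event_times_match_analytic_survival(self):
        """KM estimate of simulated conversions tracks the closed-form
        survival S(t) = exp(-Λ(t)) of the configured piecewise hazard."""
        rates = (0.05, 0.08, 0.03, 0.10)
        cfg = _deterministic_config(
            n_per_group={"MNV": 400},
            hazard_params=HazardParams(baseline_rates=rates),
            seed=5,
        )
        _, surv_df, _ = oa.simulate_cohort(cfg)
        breaks = np.array([0.0, 6.0, 12.0, 18.0, 24.0])

        def surv(t):
            expo = np.clip(t, None, breaks[1:]) - breaks[:-1]
            return np.exp(-(np.clip(expo, 0, None) * np.array(rates)).sum())

        for t in (6.0, 12.0, 18.0):
            frac_alive = (surv_df["time"] > t).mean()
            # binomial MC error at n=400 is ~0.025; allow 3 sd
            assert abs(frac_alive - surv(t)) < 0.075

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            oa.CohortConfig(n_per_group={"MNV": 0})
        with pytest.raises(ValueError):
            oa.CohortConfig(residual_sd={"ONL": -1.0, "ORB": 1, "CHOROID": 1, "CSHADE": 1})
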