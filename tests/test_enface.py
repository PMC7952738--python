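import numpy as np
import pytest
import octatlas as oa
from octatlas.enface import (
    binarize_vessels,
    enhance_projection,
    percentile_projection,
    vessel_maps,
    vesselness,
)
from octatlas.synthetic import vessel_shadow_attenuation
from octatlas.types import EnfaceMap, OctVolume


def _volume_from_windows(windows: np.ndarray, dz: float = 4.0) -> tuple[OctVolume, np.ndarray]:
    """Build a volume whose sub-RPE window holds the given values.

    ``windows`` has shape (nb, na, n_w); the RPE is placed so that the
    window [rpe-30, rpe] at window_um = (n_w-1)*dz covers exactly those
    samples.
    """
    nb, na, n_w = windows.shape
    nz = n_w + 6
    vol = np.zeros((nb, na, nz))
    vol[:, :, 3 : 3 + n_w] = windows
    rpe = np.full((nb, na), (3 + n_w - 1) * dz)
    return (
        OctVolume(intensities=vol, spacing_um=(60.0, 30.0, dz)),
        rpe,
    )


def _quantile_oracle(values, q):
    """Sort-based linear-interpolation quantile."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestPercentileProjection:
    def test_constant_window(self):
        vol, rpe = _volume_from_windows(np.full((2, 3, 8), 100.0))
        out = percentile_projection(vol, rpe, q=0.7, window_um=28.0)
        assert np.allclose(out.values, 100.0)

    def test_linear_interpolation_quantile(self):
        win = np.arange(10.0)[None, None, :]
        vol, rpe = _volume_from_windows(np.tile(win, (1, 1, 1)))
        out = percentile_projection(vol, rpe, q=0.7, window_um=36.0)
        assert out.values[0, 0] == pytest.approx(6.3)

    def test_matches_sort_oracle_on_random_windows(self, rng):
        wins = rng.uniform(0, 255, size=(4, 5, 8))
        vol, rpe = _volume_from_windows(wins)
        for q in (0.1, 0.5, 0.7, 0.9):
            out = percentile_projection(vol, rpe, q=q, window_um=28.0)
            expect = np.apply_along_axis(_quantile_oracle, -1, wins, q)
            assert np.allclose(out.values, expect, atol=1e-12)

    def test_monotone_under_constant_shift(self, rng):
        wins = rng.uniform(0, 200, size=(3, 4, 8))
        vol, rpe = _volume_from_windows(wins)
        vol2, _ = _volume_from_windows(wins + 17.0)
        a = percentile_projection(vol, rpe, window_um=28.0)
        b = percentile_projection(vol2, rpe, window_um=28.0)
        assert np.allclose(b.values - a.values, 17.0, atol=1e-9)

    def test_window_leaving_volume_marks_invalid(self):
        vol, rpe = _volume_from_windows(np.full((2, 2, 8), 50.0))
        rpe[0, 0] = 4.0  # window would start above the volume top
        out = percentile_projection(vol, rpe, window_um=28.0)
        assert not out.valid_mask[0, 0]
        assert out.valid_mask[1, 1]

    def test_rejects_bad_quantile(self):
        vol, rpe = _volume_from_windows(np.zeros((2, 2, 8)))
        with pytest.raises(ValueError):
            percentile_projection(vol, rpe, q=1.5)

    def test_shadow_is_darker_than_background(self, phantom, clean_visit, enface_grid):
        vol, _, surf = clean_visit
        proj = percentile_projection(vol, surf["BM"])
        x, y = enface_grid.coordinate_arrays()
        att = vessel_shadow_attenuation(phantom, x, y)
        assert proj.values[att > 0.3].max() < proj.values[att < 0.01].min() + 60


class TestEnhanceProjection:
    def test_constant_map_stays_flat(self):
        m = EnfaceMap(values=np.full((64, 64), 7.0), spacing_um=(30.0, 30.0))
        out = enhance_projection(m)
        assert np.nanstd(out.values) < 1e-6

    def test_isotropic_input_keeps_grid(self):
        m = EnfaceMap(values=np.random.default_rng(0).random((40, 50)), spacing_um=(30.0, 30.0))
        out = enhance_projection(m)
        assert out.values.shape == (40, 50)
        assert out.spacing_um == (30.0, 30.0)

    def test_anisotropic_input_resampled_isotropic(self):
        m = EnfaceMap(values=np.random.default_rng(0).random((40, 50)), spacing_um=(30.0, 60.0))
        out = enhance_projection(m)
        assert out.spacing_um == (30.0, 30.0)
        assert out.values.shape[0] == 80

    def test_output_in_unit_range(self, rng):
        m = EnfaceMap(values=rng.uniform(0, 255, (48, 48)), spacing_um=(30.0, 30.0))
        out = enhance_projection(m)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_vessel_contrast_to_noise_increases_on_phantom(self, phantom, noisy_visit):
        """Denoising + CLAHE raise the shadow contrast-to-noise ratio."""
        vol, _, surf = noisy_visit
        proj = percentile_projection(vol, surf["BM"])
        enh = enhance_projection(proj)

        def cnr(m):
            gx, gy = m.grid.coordinate_arrays()
            att = vessel_shadow_attenuation(phantom, gx, gy)
            shadow, bg = att > 0.3, att < 0.02
            return (m.values[bg].mean() - m.values[shadow].mean()) / m.values[bg].std()

        assert cnr(enh) > cnr(proj)

    def test_empty_valid_region_rejected(self):
        m = EnfaceMap(values=np.full((8, 8), np.nan), spacing_um=(30.0, 30.0))
        with pytest.raises(ValueError):
            enhance_projection(m)


class TestVesselness:
    def test_constant_image_zero_response(self):
        m = EnfaceMap(values=np.full((64, 64), 0.5), spacing_um=(30.0, 30.0))
        out = vesselness(m)
        assert np.allclose(out.values, 0.0)

    def test_dark_line_response_on_centerline_not_background(self):
        vals = np.ones((64, 64))
        vals[:, 31:34] = 0.2
        m = EnfaceMap(values=vals, spacing_um=(30.0, 30.0))
        out = vesselness(m)
        center = out.values[10:-10, 32]
        assert center.min() > 0.9  # strong ridge response along the line
        assert np.abs(out.values[10:-10, 10]).max() < 1e-3  # flat background

    def test_line_beats_isolated_point(self):
        line = np.ones((64, 64))
        line[:, 31:33] = 0.2
        point = np.ones((64, 64))
        point[31:33, 31:33] = 0.2
        rl = vesselness(EnfaceMap(values=line, spacing_um=(30.0, 30.0)))
        rp = vesselness(EnfaceMap(values=point, spacing_um=(30.0, 30.0)))
        assert rl.values[32, 32] > rp.values[32, 32]

    def test_default_scale_bank_covers_retinal_calibres(self):
        """Lines of 1-4 px width (30-120 µm) all respond strongly."""
        for w in (1, 2, 4):
            vals = np.ones((80, 80))
            vals[:, 38 : 38 + w] = 0.2
            m = EnfaceMap(values=vals, spacing_um=(30.0, 30.0))
            out = vesselness(m)
            assert out.values[40, 38 : 38 + w].max() > 0.5

    def test_empty_scales_rejected(self):
        m = EnfaceMap(values=np.zeros((8, 8)), spacing_um=(30.0, 30.0))
        with pytest.raises(ValueError):
            vesselness(m, scales_um=())


class TestBinarizeVessels:
    def _prob(self, arr):
        return EnfaceMap(values=arr, spacing_um=(30.0, 30.0))

    @pytest.mark.parametrize("n_px,kept", [(79, False), (80, True)])
    def test_component_size_boundary(self, n_px, kept):
        arr = np.zeros((30, 30))
        coords = np.unravel_index(np.arange(n_px), (8, 10))
        arr[coords[0] + 1, coords[1] + 1] = 0.9
        out = binarize_vessels(self._prob(arr), threshold=0.4, min_size_px=80)
        assert (out.values.sum() > 0) == kept

    def test_all_below_threshold_empty(self):
        out = binarize_vessels(self._prob(np.full((20, 20), 0.3)))
        assert out.values.sum() == 0

    def test_diagonal_pixels_count_as_one_component(self):
        arr = np.zeros((30, 30))
        for i in range(10):
            arr[i, i] = 1.0  # 8-connected diagonal line
        out = binarize_vessels(self._prob(arr), min_size_px=10)
        assert out.values.sum() == 10

    def test_rejects_out_of_range_probabilities(self):
        with pytest.raises(ValueError):
            binarize_vessels(self._prob(np.full((8, 8), 1.5)))


class TestFullRecipe:
    def test_phantom_dice_against_truth(self, phantom, noisy_visit, small_config):
        vol, _, surf = noisy_visit
        prob, binary = vessel_maps(vol, surf["BM"])
        gx, gy = prob.grid.coordinate_arrays()
        truth = vessel_shadow_attenuation(phantom, gx, gy) > 0.25
        pred = binary.values.astype(bool)
        dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())
        assert dice >= 0.7

    def test_recipe_invariant_to_affine_intensity_rescale(self, phantom, noisy_visit):
        from dataclasses import replace

        vol, _, surf = noisy_visit
        _, bin1 = vessel_maps(vol, surf["BM"])
        vol2 = replace(vol, intensities=vol.intensities * 0.5 + 20.0)
        _, bin2 = vessel_maps(vol2, surf["BM"])
        agree = (bin1.values == bin2.values).mean()
        assert agree > 0.97  # CLAHE discretization allows small differences
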