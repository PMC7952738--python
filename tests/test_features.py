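import numpy as np
import pytest

from octatlas.features import (
    DEFAULT_OFFSETS,
    GLCMatrix,
    TEXTURE_NAMES,
    choroid_texture_maps,
    compute_glcm,
    extract_choroid_patch,
    haralick,
    thickness_map,
)
from octatlas.types import LayerSurfaces, OctVolume


def _glcm_oracle(patch, dx, dz, bins=16, lo=0.0, hi=128.0):
    """Brute-force double-loop co-occurrence counting."""
    lev = np.minimum(((np.clip(patch, lo, hi) - lo) / (hi - lo) * bins).astype(int), bins - 1)
    g = np.zeros((bins, bins))
    nx, nz = patch.shape
    for i in range(nx):
        for j in range(nz):
            i2, j2 = i + dx, j + dz
            if 0 <= i2 < nx and 0 <= j2 < nz:
                g[lev[i, j], lev[i2, j2]] += 1
                g[lev[i2, j2], lev[i, j]] += 1
    return g / g.sum() if g.sum() else g


def _haralick_oracle(p):
    """Independent elementwise-summation implementation."""
    n = p.shape[0]
    energy = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    entropy = -sum(
        p[i, j] * np.log2(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0
    )
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    inertia = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    mx = sum(i * p[i, j] for i in range(n) for j in range(n))
    my = sum(j * p[i, j] for i in range(n) for j in range(n))
    shade = sum((i + j - mx - my) ** 3 * p[i, j] for i in range(n) for j in range(n))
    prom = sum((i + j - mx - my) ** 4 * p[i, j] for i in range(n) for j in range(n))
    return np.array([energy, entropy, idm, inertia, shade, prom])


class TestThicknessMap:
    def _surfaces(self, top_depth, bottom_depth, shape=(6, 8)):
        return LayerSurfaces(
            surfaces={"ILM": np.full(shape, top_depth), "BM": np.full(shape, bottom_depth)},
            spacing_um=(60.0, 30.0),
        )

    def test_flat_surfaces_constant_distance(self):
        s = self._surfaces(100.0, 160.0)
        out = thickness_map(s, "ILM", "BM")
        assert np.allclose(out.values, 60.0)
        assert out.units == "um"

    def test_identical_surfaces_zero(self):
        s = self._surfaces(120.0, 120.0)
        assert np.allclose(thickness_map(s, "ILM", "BM").values, 0.0)

    def test_missing_surface_rejected(self):
        s = self._surfaces(0.0, 1.0)
        with pytest.raises(KeyError):
            thickness_map(s, "ILM", "CHOROID_POST")

    def test_phantom_onl_field_recovered(self, phantom, clean_visit):
        _, _, surf = clean_visit
        out = thickness_map(surf, "OPL_ONL", "ONL_ORB")
        assert np.allclose(out.values, phantom.feature_mean("ONL", 0.0))

    def test_ordered_surfaces_give_nonnegative_maps(self, clean_visit):
        _, _, surf = clean_visit
        from octatlas.types import LAYER_BOUNDS

        for top, bottom in LAYER_BOUNDS.values():
            assert np.all(thickness_map(surf, top, bottom).values >= 0)


class TestExtractChoroidPatch:
    def _volume(self, nz=320, dz=3.9, fill=None):
        vals = np.zeros((4, 12, nz)) if fill is None else fill
        return OctVolume(intensities=vals, spacing_um=(60.0, 30.0, dz))

    def test_patch_depth_is_ceiling_of_um_over_dz(self):
        vol = self._volume()
        bm = np.full((4, 12), 100.0)
        patch = extract_choroid_patch(vol, bm, 1, 6)
        assert patch.shape == (5, int(np.ceil(300 / 3.9)))
        assert patch.shape[1] == 77

    def test_lateral_clamping_at_border(self):
        vol = self._volume()
        bm = np.full((4, 12), 100.0)
        patch = extract_choroid_patch(vol, bm, 0, 0)
        assert patch.shape[0] == 3  # half the window clipped away

    def test_truncated_patch_below_half_depth_invalid(self):
        vol = self._volume(nz=120)
        bm = np.full((4, 12), 110.0 * 3.9)  # only 10 samples below BM
        assert extract_choroid_patch(vol, bm, 1, 6) is None

    def test_undefined_bm_invalid(self):
        vol = self._volume()
        bm = np.full((4, 12), np.nan)
        assert extract_choroid_patch(vol, bm, 1, 6) is None

    def test_constant_volume_constant_patch(self):
        vol = self._volume(fill=np.full((4, 12, 320), 64.0))
        bm = np.full((4, 12), 100.0)
        assert np.all(extract_choroid_patch(vol, bm, 2, 5) == 64.0)


class TestComputeGlcm:
    def test_single_pair_hand_enumeration(self):
        patch = np.array([[0.0], [127.0]])  # two laterally adjacent pixels
        (g,) = compute_glcm(patch, offsets=[(1, 0)])
        expect = np.zeros((16, 16))
        expect[0, 15] = expect[15, 0] = 0.5
        assert np.array_equal(g.probabilities, expect)

    def test_constant_patch_single_diagonal_entry(self):
        (g,) = compute_glcm(np.full((5, 9), 60.0), offsets=[(1, 0)])
        lev = int(60.0 / 128.0 * 16)
        assert g.probabilities[lev, lev] == 1.0
        assert g.probabilities.sum() == 1.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            patch = rng.uniform(0, 160, size=(8, 8))  # includes out-of-range values
            glcms = compute_glcm(patch, offsets=DEFAULT_OFFSETS)
            for (dx, dz), g in zip(DEFAULT_OFFSETS, glcms):
                assert np.allclose(g.probabilities, _glcm_oracle(patch, dx, dz), atol=1e-15)

    def test_normalization_sums_to_one(self, rng):
        patch = rng.uniform(0, 128, size=(5, 77))
        for g in compute_glcm(patch):
            assert g.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_oversized_offset_marked_empty(self):
        (g,) = compute_glcm(np.zeros((2, 3)), offsets=[(5, 0)])
        assert g.empty

    def test_values_above_range_clipped_to_top_bin(self):
        (g,) = compute_glcm(np.array([[300.0], [300.0]]), offsets=[(1, 0)])
        assert g.probabilities[15, 15] == 1.0


class TestHaralick:
    def test_degenerate_single_entry(self):
        (g,) = compute_glcm(np.full((4, 4), 10.0), offsets=[(1, 0)])
        d = haralick(g)
        assert d.energy == 1.0
        assert d.entropy == 0.0
        assert d.inertia == 0.0
        assert d.inverse_difference_moment == 1.0
        assert d.cluster_shade == 0.0
        assert d.cluster_prominence == 0.0

    def test_two_cell_glcm_hand_values(self):
        p = np.zeros((16, 16))
        p[0, 15] = p[15, 0] = 0.5
        d = haralick(GLCMatrix(p))
        assert d.energy == pytest.approx(0.5)
        assert d.entropy == pytest.approx(1.0)  # one bit
        assert d.inertia == pytest.approx(225.0)
        # both cells have |i-j| = 15: IDM = 2 * 0.5 / (1 + 225)
        assert d.inverse_difference_moment == pytest.approx(1.0 / 226.0)
        assert d.cluster_shade == pytest.approx(0.0)  # µx = µy = 7.5, i+j-15 = 0
        assert d.cluster_prominence == pytest.approx(0.0)

    def test_matches_summation_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, (16, 16))
            p = (p + p.T) / 2
            p /= p.sum()
            d = haralick(GLCMatrix(p)).as_array()
            # both in order: energy, entropy, idm, inertia, shade, prominence
            assert np.allclose(d, _haralick_oracle(p), atol=1e-12)

    def test_symmetric_about_mean_glcm_has_zero_shade(self, rng):
        """Cluster shade is a third central moment: it vanishes for any
        GLCM whose i+j distribution is symmetric about its mean."""
        p = np.zeros((16, 16))
        p[2, 4] = p[4, 2] = 0.25  # i+j = 6
        p[8, 10] = p[10, 8] = 0.25  # i+j = 18, symmetric about 12
        assert haralick(GLCMatrix(p)).cluster_shade == pytest.approx(0.0, abs=1e-12)

    def test_empty_glcm_rejected(self):
        with pytest.raises(ValueError):
            haralick(GLCMatrix(np.zeros((16, 16)), empty=True))


class TestChoroidTextureMaps:
    def test_constant_below_bm_gives_flat_degenerate_maps(self):
        vals = np.full((3, 10, 160), 64.0)
        vol = OctVolume(intensities=vals, spacing_um=(60.0, 30.0, 3.9))
        bm = np.full((3, 10), 20.0 * 3.9)
        maps = choroid_texture_maps(vol, bm)
        valid = maps["entropy"].valid_mask
        assert valid.any()
        assert np.allclose(maps["entropy"].values[valid], 0.0)
        assert np.allclose(maps["energy"].values[valid], 1.0)

    def test_noise_variance_zones_separated_by_inertia(self, rng):
        nz = 160
        vals = np.full((3, 20, nz), 64.0)
        vals[:, :10] += rng.normal(0, 4, (3, 10, nz))
        vals[:, 10:] += rng.normal(0, 24, (3, 10, nz))
        vol = OctVolume(intensities=np.clip(vals, 0, 255), spacing_um=(60.0, 30.0, 3.9))
        bm = np.full((3, 20), 20.0 * 3.9)
        maps = choroid_texture_maps(vol, bm)
        inertia = maps["inertia"].values
        quiet = inertia[:, 2:8].ravel()
        loud = inertia[:, 12:18].ravel()
        pooled_sd = np.sqrt((quiet.var() + loud.var()) / 2)
        assert loud.mean() - quiet.mean() > 3 * pooled_sd

    def test_descriptor_rotation_stability_on_isotropic_texture(self, rng):
        """Swapping the lateral/axial roles of the offsets changes the
        averaged descriptors little when the texture statistics are
        isotropic in physical units."""
        nz = 160
        vals = np.clip(np.full((3, 20, nz), 64.0) + rng.normal(0, 15, (3, 20, nz)), 0, 255)
        vol = OctVolume(intensities=vals, spacing_um=(60.0, 30.0, 3.9))
        bm = np.full((3, 20), 20.0 * 3.9)
        normal = choroid_texture_maps(vol, bm)
        swapped = choroid_texture_maps(
            vol, bm, offsets=((0, 6), (1, 0), (1, 6), (1, -6))
        )
        for name in TEXTURE_NAMES:
            a = normal[name].values[normal[name].valid_mask].mean()
            b = swapped[name].values[swapped[name].valid_mask].mean()
            scale = max(abs(a), abs(b), 1e-9)
            assert abs(a - b) / scale < 0.05

    def test_all_nan_bm_rejected(self):
        vol = OctVolume(intensities=np.zeros((2, 4, 80)), spacing_um=(60.0, 30.0, 3.9))
        with pytest.raises(ValueError):
            choroid_texture_maps(vol, np.full((2, 4), np.nan))
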