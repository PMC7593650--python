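"""Image-space geometry operators: smoothing, thresholding, mask algebra."""

import numpy as np
import pytest
from scipy import ndimage

from kneefem.image import LabelMask, VoxelImage
from kneefem import imageproc as ip


def _img(values, spacing=10.0):
    return VoxelImage(np.asarray(values, dtype=float), spacing)


def _mask(values, spacing=10.0, tissue="femur_bone"):
    return LabelMask(np.asarray(values, dtype=bool), spacing, tissue=tissue)


class TestGaussianSmooth:
    def test_constant_image_unchanged(self):
        img = _img(np.full((8, 8, 8), 3.7))
        out = ip.gaussian_smooth(img, 1.0)
        np.testing.assert_allclose(out.values, 3.7)

    def test_impulse_matches_explicit_kernel(self):
        """Unit impulse response equals the directly evaluated separable
        discrete Gaussian (the same truncated kernel scipy uses)."""
        n = 21
        vals = np.zeros((n, n, n))
        vals[n // 2, n // 2, n // 2] = 1.0
        sigma = 1.0
        out = ip.gaussian_smooth(_img(vals), sigma)
        r = int(4 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()
        expected = (k[:, None, None] * k[None, :, None] * k[None, None, :])
        c = n // 2
        sub = out.values[c - r:c + r + 1, c - r:c + r + 1, c - r:c + r + 1]
        np.testing.assert_allclose(sub, expected, atol=1e-12)

    def test_mean_preserved(self, rng):
        img = _img(rng.normal(100.0, 20.0, (16, 16, 16)))
        out = ip.gaussian_smooth(img, 1.0)
        assert abs(out.values.mean() - img.values.mean()) \
            <= 1e-6 * abs(img.values.mean())

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            ip.gaussian_smooth(_img(np.zeros((4, 4, 4))), 0.0)


class TestThreshold:
    def test_bimodal_counting(self):
        vals = np.concatenate([np.full(100, 10.0), np.full(50, 200.0)])
        img = _img(np.pad(vals, (0, 150 - len(vals) % 150))[:125].reshape(5, 5, 5))
        # build exactly: 100 voxels at 10, 25 at 200 -> use a 5x5x5 block
        vals = np.full(125, 10.0)
        vals[:50] = 200.0
        img = _img(vals.reshape(5, 5, 5))
        mask = ip.threshold_segment(img, 100.0)
        assert mask.count == 50

    def test_level_at_min_gives_full_mask(self):
        img = _img(np.arange(27.0).reshape(3, 3, 3))
        assert ip.threshold_segment(img, 0.0).count == 27

    def test_empty_mask_warns(self):
        img = _img(np.zeros((3, 3, 3)))
        with pytest.warns(UserWarning):
            ip.threshold_segment(img, 10.0)

    def test_phantom_bone_dice(self, coarse_phantom):
        """Smoothed single-level threshold recovers the bone mask with
        Dice >= 0.95 against the generating truth."""
        rest, _, _, truth = coarse_phantom
        smooth = ip.gaussian_smooth(rest, 1.0)
        level = ip.suggest_threshold(smooth)
        mask = ip.threshold_segment(smooth, level)
        truth_bone = (truth.masks["femur_bone"].values
                      | truth.masks["tibia_bone"].values
                      | truth.masks["calcified_meniscus"].values)
        inter = (mask.values & truth_bone).sum()
        dice = 2 * inter / (mask.count + truth_bone.sum())
        assert dice >= 0.95


class TestSuggestThreshold:
    def test_level_between_two_modes(self, rng):
        vals = np.where(rng.random((12, 12, 12)) < 0.5, 10.0, 200.0)
        level = ip.suggest_threshold(_img(vals))
        assert 10.0 < level < 200.0

    def test_constant_image_errors(self):
        with pytest.raises(ip.ThresholdError):
            ip.suggest_threshold(_img(np.full((6, 6, 6), 5.0)))


class TestMaskBoolean:
    def test_matches_set_oracle_exhaustively(self, rng):
        """Voxelwise ops agree with python-set semantics on random masks."""
        for _ in range(5):
            a_vals = rng.random((20, 20, 20)) < 0.3
            b_vals = rng.random((20, 20, 20)) < 0.3
            a, b = _mask(a_vals), _mask(b_vals)
            set_a = {tuple(i) for i in np.argwhere(a_vals)}
            set_b = {tuple(i) for i in np.argwhere(b_vals)}
            for op, oracle in (("subtract", set_a - set_b),
                               ("union", set_a | set_b),
                               ("intersect", set_a & set_b)):
                got = {tuple(i) for i in
                       np.argwhere(ip.mask_boolean(a, b, op).values)}
                assert got == oracle, op

    def test_set_identities(self, rng):
        a = _mask(rng.random((10, 10, 10)) < 0.4)
        b = _mask(rng.random((10, 10, 10)) < 0.4)
        assert ip.mask_boolean(a, a, "subtract").count == 0
        np.testing.assert_array_equal(
            ip.mask_boolean(a, b, "union").values,
            ip.mask_boolean(b, a, "union").values)
        # subtract(a,b) disjoint from b
        assert (ip.mask_boolean(a, b, "subtract").values & b.values).sum() == 0

    def test_grid_mismatch_rejected(self):
        a = _mask(np.ones((4, 4, 4), bool), spacing=10.0)
        b = _mask(np.ones((4, 4, 4), bool), spacing=20.0)
        with pytest.raises(ValueError):
            ip.mask_boolean(a, b, "union")

    def test_phantom_shell_recovery(self, clean_phantom):
        """subtract(cartilage|bone, bone) leaves exactly the cartilage."""
        _, (rest, sf, st, truth) = clean_phantom
        cart = truth.masks["femur_cartilage"]
        bone = truth.masks["femur_bone"]
        both = ip.mask_boolean(cart, bone, "union")
        back = ip.mask_boolean(both, bone, "subtract")
        np.testing.assert_array_equal(back.values, cart.values)


class TestMaskSmooth:
    def test_cube_volume_within_10pct(self):
        vals = np.zeros((30, 30, 30), bool)
        vals[5:25, 5:25, 5:25] = True
        out = ip.mask_smooth(_mask(vals), 2.0)
        assert abs(out.count - vals.sum()) <= 0.10 * vals.sum()

    def test_smooth_ball_nearly_unchanged(self):
        z = np.arange(40) - 19.5
        d2 = z[:, None, None]**2 + z[None, :, None]**2 + z[None, None, :]**2
        ball = d2 <= 14**2
        out = ip.mask_smooth(_mask(ball), 2.0)
        dice = 2 * (out.values & ball).sum() / (out.count + ball.sum())
        assert dice >= 0.98

    def test_tiny_mask_emptied_errors(self):
        vals = np.zeros((10, 10, 10), bool)
        vals[5, 5, 5] = True
        with pytest.raises(ValueError):
            ip.mask_smooth(_mask(vals), 2.0)


class TestWrapMeniscus:
    def _slabs(self):
        shape = (20, 20, 21)
        fem = np.zeros(shape, bool)
        tib = np.zeros(shape, bool)
        calc = np.zeros(shape, bool)
        tib[:, :, 4:6] = True       # lower slab
        fem[:, :, 11:13] = True     # upper slab, 5-voxel gap
        calc[8:12, 8:12, 7:10] = True  # block in the gap
        sp = 10.0
        return (_mask(calc, sp, "calcified_meniscus"),
                _mask(fem, sp, "femur_cartilage"),
                _mask(tib, sp, "tibia_cartilage"))

    def test_gap_fill_matches_closing_oracle(self):
        calc, fem, tib = self._slabs()
        max_gap_um = 100.0  # 10 voxels
        out = ip.wrap_meniscus(calc, fem, tib, max_gap_um,
                               superior_clearance_voxels=0)
        # oracle: explicit closing of the union with the same ball, minus
        # inputs, restricted to components touching the calcified mask
        union = calc.values | fem.values | tib.values
        r = 5
        zz = np.arange(-r, r + 1)
        ball = (zz[:, None, None]**2 + zz[None, :, None]**2
                + zz[None, None, :]**2) <= r**2
        fill = ndimage.binary_erosion(
            ndimage.binary_dilation(union, ball), ball) & ~union
        lab, n = ndimage.label(fill, np.ones((3, 3, 3)))
        near = ndimage.binary_dilation(calc.values, np.ones((3, 3, 3)))
        keep = np.zeros(n + 1, bool)
        keep[np.unique(lab[near])[1:]] = True
        np.testing.assert_array_equal(out.values, keep[lab])
        assert out.count > 0

    def test_output_disjoint_from_inputs(self):
        calc, fem, tib = self._slabs()
        out = ip.wrap_meniscus(calc, fem, tib, 120.0)
        for m in (calc, fem, tib):
            assert (out.values & m.values).sum() == 0

    def test_superior_clearance_keeps_gap_to_femoral_surface(self):
        from scipy import ndimage

        calc, fem, tib = self._slabs()
        out = ip.wrap_meniscus(calc, fem, tib, 120.0,
                               superior_clearance_voxels=2)
        near_femur = ndimage.binary_dilation(fem.values, iterations=2)
        assert (out.values & near_femur).sum() == 0

    def test_zero_gap_is_empty(self):
        calc, fem, tib = self._slabs()
        with pytest.warns(UserWarning):
            out = ip.wrap_meniscus(calc, fem, tib, 0.0)
        assert out.count == 0


class TestGenericCartilage:
    def _parallel_slabs(self, gap_vox=8, spacing=10.0):
        shape = (24, 24, 30)
        fem = np.zeros(shape, bool)
        tib = np.zeros(shape, bool)
        tib[:, :, 2:8] = True
        fem[:, :, 8 + gap_vox:8 + gap_vox + 6] = True
        return (_mask(fem, spacing, "femur_bone"),
                _mask(tib, spacing, "tibia_bone"), gap_vox * spacing * 1e-3)

    def test_slab_thickness_half_gap(self):
        """Two layers of equal thickness t fill a bone gap g when they just
        touch, hence t = g/2."""
        fem, tib, gap_mm = self._parallel_slabs()
        gen = ip.build_generic_cartilage(fem, tib, "one_thickness")
        assert abs(gen.thickness_lateral_mm - gap_mm / 2) <= fem.spacing_mm

    def test_phantom_two_thickness_ordering(self, clean_phantom):
        """Medial bone gap exceeds lateral, so the medial layers are thicker."""
        _, (rest, sf, st, truth) = clean_phantom
        gen = ip.build_generic_cartilage(truth.masks["femur_bone"],
                                         truth.masks["tibia_bone"],
                                         "two_thickness")
        assert gen.thickness_medial_mm > gen.thickness_lateral_mm

    def test_shell_thickness_matches_returned_t(self):
        fem, tib, gap_mm = self._parallel_slabs()
        gen = ip.build_generic_cartilage(fem, tib, "one_thickness")
        # distance-transform thickness of the flat femoral layer
        edt = ndimage.distance_transform_edt(
            gen.femur_cartilage.values, sampling=fem.spacing_mm)
        thick = 2.0 * edt.max()
        assert abs(thick - gen.thickness_lateral_mm) <= 1.5 * fem.spacing_mm

    def test_touching_bones_rejected(self):
        a = _mask(np.ones((4, 4, 4), bool), tissue="femur_bone")
        with pytest.raises(ValueError):
            ip.build_generic_cartilage(a, a, "one_thickness")


class TestTranslateMask:
    def test_identity_and_involution(self, rng):
        m = _mask(rng.random((12, 12, 12)) < 0.3)
        same = ip.translate_mask(m, (0, 0, 0))
        np.testing.assert_array_equal(same.values, m.values)
        shifted = ip.translate_mask(m, (3, -2, 5))
        back = ip.translate_mask(shifted, (-3, 2, -5))
        # compare as physical point sets (origins may differ after padding)
        def points(mask):
            idx = np.argwhere(mask.values)
            return {tuple(np.round(mask.origin_mm + mask.spacing_mm * i, 9))
                    for i in idx}
        assert points(back) == points(m)

    def test_volume_preserved_with_padding(self):
        vals = np.zeros((5, 5, 5), bool)
        vals[4, 4, 4] = True
        out = ip.translate_mask(_mask(vals), (3, 3, 3))
        assert out.count == 1

    def test_87_um_is_5_voxels_at_17_4(self):
        assert round(87.0 / 17.4) == 5
        m = _mask(np.ones((6, 6, 12), bool), spacing=17.4)
        out = ip.translate_mask(m, (0, 0, 5))
        zs = np.argwhere(out.values)[:, 2]
        assert zs.min() == 5


class TestSeparateBones:
    def test_phantom_components(self, coarse_phantom):
        rest, _, _, truth = coarse_phantom
        smooth = ip.gaussian_smooth(rest, 1.0)
        mask = ip.threshold_segment(smooth, ip.suggest_threshold(smooth))
        parts = ip.separate_bone_components(mask)
        # femur reaches highest, tibia lowest
        fz = np.argwhere(parts["femur_bone"].values)[:, 2]
        tz = np.argwhere(parts["tibia_bone"].values)[:, 2]
        assert fz.max() > tz.max() and tz.min() < fz.min()
        assert parts["calcified_meniscus"].count > 0
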