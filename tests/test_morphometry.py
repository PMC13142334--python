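"""Morphometry: background, fusion, segmentation, lengths and indices."""

import math

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from musclekit import morphometry as mm
from musclekit.synthetic import (ImageSceneParams, gen_cross_section,
                                 gen_culture_scene)


def _culture_mask(img):
    d = img["desmin"]
    return d > threshold_otsu(d)


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        out = mm.subtract_background(np.full((128, 128), 37.0), radius=20)
        assert np.allclose(out, 0.0)

    def test_all_zero_stays_zero(self):
        out = mm.subtract_background(np.zeros((64, 64)), radius=10)
        assert np.allclose(out, 0.0)

    def test_disk_preserved_offset_removed(self):
        """A bright disk much smaller than the kernel survives; the constant
        offset is removed (compare against the analytic residual)."""
        img = np.full((256, 256), 20.0)
        rr, cc = np.ogrid[:256, :256]
        disk = (rr - 128) ** 2 + (cc - 128) ** 2 <= 12 ** 2
        img[disk] += 100.0
        out = mm.subtract_background(img, radius=50)
        inner = (rr - 128) ** 2 + (cc - 128) ** 2 <= 8 ** 2
        far = (rr - 128) ** 2 + (cc - 128) ** 2 >= 60 ** 2
        assert np.allclose(out[inner], 100.0, atol=2.0)
        assert np.allclose(out[far], 0.0, atol=2.0)


class TestFuseChannels:
    def test_identical_channels_identity(self, rng):
        a = rng.random((64, 64))
        assert np.allclose(mm.fuse_channels(a, a), a)

    def test_one_channel_zero_halves(self, rng):
        a = rng.random((64, 64))
        assert np.allclose(mm.fuse_channels(a, np.zeros_like(a)), a / 2)

    def test_matches_per_pixel_oracle(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        fused = mm.fuse_channels(a, b)
        for i, j in [(0, 0), (5, 7), (31, 31), (16, 2)]:
            assert fused[i, j] == pytest.approx((a[i, j] + b[i, j]) / 2)
        oracle = np.empty_like(a)
        for i in range(32):
            for j in range(32):
                oracle[i, j] = (a[i, j] + b[i, j]) / 2
        assert np.allclose(fused, oracle)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mm.fuse_channels(np.zeros((4, 4)), np.zeros((5, 5)))


class TestSegmentMyotubes:
    def test_blank_image_zero_objects(self):
        seg = mm.segment_myotubes(np.zeros((128, 128)), pixel_size=1.0)
        assert seg.n_objects == 0
        assert seg.effective_csa_mm2 == 0.0

    def test_noise_free_scene_recovers_count_and_csa(self):
        p = ImageSceneParams(image_size=(512, 512), pixel_size=0.65,
                             n_objects=8, seed=3, noise_sd=0.0)
        img, gt = gen_cross_section(p)
        fused = mm.fuse_channels(img["myosin"], img["actin"])
        seg = mm.segment_myotubes(fused, 0.65)
        assert seg.n_objects == gt["n_objects"]
        assert seg.effective_csa_mm2 == pytest.approx(gt["csa_mm2"], rel=0.05)

    def test_noisy_scene_csa_within_10pct(self):
        p = ImageSceneParams(image_size=(512, 512), pixel_size=0.65,
                             n_objects=8, seed=3, noise_sd=20.0)
        img, gt = gen_cross_section(p)
        fused = mm.fuse_channels(mm.subtract_background(img["myosin"], 60),
                                 mm.subtract_background(img["actin"], 60))
        seg = mm.segment_myotubes(fused, 0.65)
        assert seg.effective_csa_mm2 == pytest.approx(gt["csa_mm2"], rel=0.10)

    def test_touching_disks_split_with_area_conserved(self):
        p = ImageSceneParams(image_size=(256, 256), pixel_size=1.0, seed=0,
                             noise_sd=0.0,
                             object_specs=[{"center": (128, 100), "radius_px": 30},
                                           {"center": (128, 160), "radius_px": 30}],
                             n_background_nuclei=0)
        img, gt = gen_cross_section(p)
        fused = mm.fuse_channels(img["myosin"], img["actin"])
        seg = mm.segment_myotubes(fused, 1.0)
        assert seg.n_objects == 2
        assert seg.areas_um2.sum() == pytest.approx(gt["total_area_um2"],
                                                    rel=0.02)

    def test_csa_invariant_to_translation(self):
        spec = [{"center": (90, 90), "radius_px": 25}]
        shifted = [{"center": (150, 160), "radius_px": 25}]
        csas = []
        for s in (spec, shifted):
            p = ImageSceneParams(image_size=(256, 256), pixel_size=1.0, seed=0,
                                 noise_sd=0.0, object_specs=s,
                                 n_background_nuclei=0)
            img, _ = gen_cross_section(p)
            csas.append(mm.segment_myotubes(img["myosin"], 1.0).effective_csa_mm2)
        assert csas[0] == pytest.approx(csas[1], rel=1e-9)

    def test_area_scales_with_pixel_size_squared(self):
        p = ImageSceneParams(image_size=(256, 256), pixel_size=1.0, seed=0,
                             noise_sd=0.0,
                             object_specs=[{"center": (128, 128), "radius_px": 40}],
                             n_background_nuclei=0)
        img, _ = gen_cross_section(p)
        fused = mm.fuse_channels(img["myosin"], img["actin"])
        a1 = mm.segment_myotubes(fused, 1.0).areas_um2[0]
        a2 = mm.segment_myotubes(fused, 2.0).areas_um2[0]
        assert a2 == pytest.approx(4 * a1)

    def test_min_area_filter_drops_small_objects(self):
        p = ImageSceneParams(image_size=(256, 256), pixel_size=1.0, seed=0,
                             noise_sd=0.0,
                             object_specs=[{"center": (64, 64), "radius_px": 30},
                                           {"center": (180, 180), "radius_px": 4}],
                             n_background_nuclei=0)
        img, _ = gen_cross_section(p)
        fused = mm.fuse_channels(img["myosin"], img["actin"])
        seg = mm.segment_myotubes(fused, 1.0, min_area_um2=100.0)
        assert seg.n_objects == 1


class TestDesminFraction:
    def test_blank_zero(self):
        r = mm.desmin_positive_fraction(np.zeros((64, 64)))
        assert r["fraction"] == 0.0 and r["area_um2"] == 0.0

    def test_half_bright_half_dark(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 100.0
        r = mm.desmin_positive_fraction(img, pixel_size=1.0)
        assert r["fraction"] == pytest.approx(0.5)
        assert r["area_um2"] == pytest.approx(64 * 32)

    def test_synthetic_scene_within_5pct(self):
        p = ImageSceneParams(image_size=(512, 512), pixel_size=0.65,
                             n_objects=5, seed=4, noise_sd=5.0)
        img, gt = gen_culture_scene(p)
        r = mm.desmin_positive_fraction(img["desmin"], 0.65)
        assert r["fraction"] == pytest.approx(gt["desmin_area_fraction"],
                                              rel=0.05)


class TestConversionAndFusion:
    def test_no_desmin_gives_zero(self):
        mask = np.zeros((64, 64), dtype=bool)
        cents = np.array([[10, 10], [20, 20], [30, 30]])
        assert mm.conversion_efficiency(mask, cents) == 0.0
        assert mm.fusion_index(mask, cents) == 0.0

    def test_all_nuclei_inside_gives_one(self):
        mask = np.ones((64, 64), dtype=bool)
        cents = np.array([[10, 10], [20, 20]])
        assert mm.conversion_efficiency(mask, cents) == 1.0
        # single syncytium holding all nuclei
        assert mm.fusion_index(mask, cents) == 1.0

    def test_mononucleated_objects_zero_fusion(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:15, 5:15] = True
        mask[40:50, 40:50] = True
        cents = np.array([[10, 10], [45, 45]])
        assert mm.conversion_efficiency(mask, cents) == 1.0
        assert mm.fusion_index(mask, cents) == 0.0

    def test_synthetic_scene_exact_ground_truth(self):
        p = ImageSceneParams(image_size=(640, 640), pixel_size=0.65,
                             n_objects=5, seed=7, noise_sd=0.0,
                             n_background_nuclei=15)
        img, gt = gen_culture_scene(p)
        mask = _culture_mask(img)
        cents = np.array(gt["nuclei_centroids"])
        assert mm.conversion_efficiency(mask, cents) == pytest.approx(
            gt["conversion_efficiency"], abs=1e-12)
        assert mm.fusion_index(mask, cents) == pytest.approx(
            gt["fusion_index"], abs=1e-12)

    def test_invariant_to_object_relabeling(self):
        """Mirroring the scene permutes object labels but leaves the
        nuclear indices unchanged."""
        p = ImageSceneParams(image_size=(512, 512), pixel_size=1.0,
                             n_objects=4, seed=12, noise_sd=0.0,
                             n_background_nuclei=8)
        img, gt = gen_culture_scene(p)
        mask = _culture_mask(img)
        cents = np.array(gt["nuclei_centroids"])
        flipped_mask = mask[::-1, :]
        flipped_cents = cents.copy()
        flipped_cents[:, 0] = mask.shape[0] - 1 - cents[:, 0]
        assert mm.fusion_index(mask, cents) == pytest.approx(
            mm.fusion_index(flipped_mask, flipped_cents))
        assert mm.conversion_efficiency(mask, cents) == pytest.approx(
            mm.conversion_efficiency(flipped_mask, flipped_cents))

    def test_empty_nuclei_rejected(self):
        with pytest.raises(ValueError):
            mm.conversion_efficiency(np.zeros((8, 8), bool), np.empty((0, 2)))


class TestLengths:
    @pytest.mark.parametrize("spec,expect,tol", [
        ({"kind": "straight", "start": (256, 56), "angle_deg": 0,
          "length_px": 400, "width_px": 10}, 400.0, 2.0),
        ({"kind": "arc", "center": (450, 60), "radius_px": 200,
          "theta0_deg": -90, "theta1_deg": 0, "width_px": 10},
         100 * math.pi, 100 * math.pi * 0.03),
        ({"kind": "straight", "start": (100, 50), "angle_deg": 22.5,
          "length_px": 400, "width_px": 10}, 400.0, 400 * 0.03),
    ])
    def test_known_geometry(self, spec, expect, tol):
        p = ImageSceneParams(image_size=(512, 512), pixel_size=1.0, seed=0,
                             noise_sd=0.0, tube_specs=[dict(spec, n_nuclei=0)],
                             n_background_nuclei=0)
        img, _ = gen_culture_scene(p)
        lengths, _ = mm.myotube_lengths(_culture_mask(img), 1.0)
        assert lengths.size == 1
        assert abs(lengths[0] - expect) <= tol

    def test_pct_over_300(self):
        specs = [{"kind": "straight", "start": (100, 50), "angle_deg": 0,
                  "length_px": 250, "width_px": 8, "n_nuclei": 0},
                 {"kind": "straight", "start": (300, 50), "angle_deg": 0,
                  "length_px": 350, "width_px": 8, "n_nuclei": 0}]
        p = ImageSceneParams(image_size=(512, 512), pixel_size=1.0, seed=0,
                             noise_sd=0.0, tube_specs=specs,
                             n_background_nuclei=0)
        img, _ = gen_culture_scene(p)
        lengths, pct = mm.myotube_lengths(_culture_mask(img), 1.0)
        assert pct == pytest.approx(50.0)

    def test_length_scales_with_pixel_size(self):
        p = ImageSceneParams(image_size=(512, 512), pixel_size=1.0, seed=0,
                             noise_sd=0.0,
                             tube_specs=[{"kind": "straight", "start": (256, 56),
                                          "angle_deg": 0, "length_px": 400,
                                          "width_px": 10, "n_nuclei": 0}],
                             n_background_nuclei=0)
        img, _ = gen_culture_scene(p)
        mask = _culture_mask(img)
        l1, _ = mm.myotube_lengths(mask, 1.0)
        l2, _ = mm.myotube_lengths(mask, 0.5)
        assert l2[0] == pytest.approx(0.5 * l1[0])

    def test_widths_approximate_tube_width(self):
        p = ImageSceneParams(image_size=(512, 512), pixel_size=1.0, seed=0,
                             noise_sd=0.0,
                             tube_specs=[{"kind": "straight", "start": (256, 56),
                                          "angle_deg": 0, "length_px": 400,
                                          "width_px": 12, "n_nuclei": 0}],
                             n_background_nuclei=0)
        img, _ = gen_culture_scene(p)
        w = mm.myotube_widths(_culture_mask(img), 1.0)
        assert w.size == 1
        assert w[0] == pytest.approx(12.0, rel=0.25)


class TestMaskedIntensity:
    def test_constant_in_mask(self):
        img = np.full((32, 32), 10.0)
        mask = np.zeros((32, 32), bool)
        mask[4:10, 4:10] = True
        assert mm.masked_mean_intensity(img, mask) == pytest.approx(10.0)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mm.masked_mean_intensity(np.ones((8, 8)), np.zeros((8, 8), bool))

    def test_two_level_image_matches_pixel_oracle(self, rng):
        img = rng.random((48, 48)) * 50
        mask = rng.random((48, 48)) > 0.6
        expected = 0.0
        n = 0
        for i in range(48):
            for j in range(48):
                if mask[i, j]:
                    expected += img[i, j]
                    n += 1
        assert mm.masked_mean_intensity(img, mask) == pytest.approx(expected / n)


class TestRegistration:
    def test_recovers_integer_shift(self, rng):
        ref = rng.random((128, 128))
        ref[40:60, 50:80] += 3.0
        moved = np.roll(ref, (5, -7), axis=(0, 1))
        aligned, shift = mm.register_translation(ref, moved)
        assert shift == (-5, 7)
        assert np.allclose(aligned, ref)
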