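"""Imaging pipeline: segmentation, statistics and shape oracles."""

import numpy as np
import pytest
from scipy import ndimage

from eggid.imaging import (
    CalibratedEggImage,
    colour_stats,
    correct_illumination,
    detect_blunt_end,
    egg_width_px,
    extract_features,
    granularity_spectrum,
    luminance_histogram,
    partition_regions,
    pattern_scales,
    segment_spots,
    shape_metrics,
    shrink_mask,
    spot_metrics,
)
from eggid.simulate import ImageSynthConfig, render_egg_image


def _uniform_egg(value=0.5, h=120, w=200):
    y, x = np.mgrid[0:h, 0:w]
    mask = ((x - w / 2) / (w / 2 - 10)) ** 2 + ((y - h / 2) / (h / 2 - 10)) ** 2 < 1
    channels = {ch: np.full((h, w), value) for ch in ("R", "G", "B", "UV", "LUM")}
    return CalibratedEggImage(channels=channels, mask=mask, scale=10.0)


# ---------------------------------------------------------------------------
# Illumination correction
# ---------------------------------------------------------------------------


class TestCorrectIllumination:
    def test_flat_field_is_identity(self):
        img = _uniform_egg(0.5)
        out = correct_illumination(img, blur_radius_px=64)
        assert np.allclose(out.channels["LUM"], 0.5, atol=1e-6)

    def test_gradient_cv_strictly_decreases(self):
        h = w = 512
        y, x = np.mgrid[0:h, 0:w]
        mask = ((x - 256) / 200.0) ** 2 + ((y - 256) / 140.0) ** 2 < 1
        grad = 0.3 + 0.4 * x / (w - 1)
        img = CalibratedEggImage(
            channels={ch: grad.copy() for ch in ("R", "G", "B", "UV", "LUM")},
            mask=mask,
            scale=10.0,
        )
        out = correct_illumination(img, blur_radius_px=2048)
        def cv(a):
            v = a[mask]
            return v.std() / v.mean()
        assert cv(out.channels["LUM"]) < cv(img.channels["LUM"])

    def test_huge_radius_small_crop_no_error(self):
        img = _uniform_egg(0.5, h=200, w=300)
        out = correct_illumination(img, blur_radius_px=2048)
        assert out.channels["LUM"].shape == (200, 300)

    def test_empty_mask_raises(self):
        img = _uniform_egg(0.5)
        img.mask[:] = False
        with pytest.raises(ValueError, match="no egg pixels"):
            correct_illumination(img)


# ---------------------------------------------------------------------------
# Mask shrinking
# ---------------------------------------------------------------------------


class TestShrinkMask:
    def test_disk_erosion_radius(self):
        y, x = np.mgrid[0:256, 0:256]
        disk = (x - 128) ** 2 + (y - 128) ** 2 <= 100**2
        out = shrink_mask(disk, egg_width_px=200.0, fraction=0.03)
        # radius should shrink by round(0.03 * 200) = 6 px
        area = out.sum()
        assert abs(np.sqrt(area / np.pi) - 94) < 1.5

    def test_zero_fraction_identity(self):
        y, x = np.mgrid[0:64, 0:64]
        disk = (x - 32) ** 2 + (y - 32) ** 2 <= 20**2
        assert np.array_equal(shrink_mask(disk, 40.0, fraction=0.0), disk)

    def test_ellipse_area_strictly_decreases(self, spotted_egg):
        egg, _, _ = spotted_egg
        out = shrink_mask(egg.mask, egg_width_px(egg.mask), 0.03)
        assert out.sum() < egg.mask.sum()
        assert not np.any(out & ~egg.mask)

    def test_overshrink_raises(self):
        y, x = np.mgrid[0:32, 0:32]
        disk = (x - 16) ** 2 + (y - 16) ** 2 <= 3**2
        with pytest.raises(ValueError, match="too small"):
            shrink_mask(disk, egg_width_px=500.0, fraction=0.5)


# ---------------------------------------------------------------------------
# Spot segmentation
# ---------------------------------------------------------------------------


class TestSegmentSpots:
    def test_spotless_egg_zero_components(self):
        img = _uniform_egg(0.8)
        seg = segment_spots(img)
        assert seg.n_spots == 0

    def test_counts_rendered_spots_exactly(self, spotted_egg):
        egg, truth, cfg = spotted_egg
        corrected = correct_illumination(egg)
        seg = segment_spots(corrected)
        assert seg.n_spots == cfg.n_spots
        inter = (seg.spot_mask & truth).sum()
        union = (seg.spot_mask | truth).sum()
        assert inter / union > 0.8

    def test_gradient_plus_correction_preserves_count(self, spotted_egg):
        _, _, cfg = spotted_egg
        cfg_grad = ImageSynthConfig(**{**cfg.__dict__, "gradient_amplitude": 0.3})
        egg_g, _ = render_egg_image(cfg_grad)
        seg = segment_spots(correct_illumination(egg_g))
        assert seg.n_spots == cfg.n_spots

    @pytest.mark.parametrize("factor", [0.6, 0.8, 1.2, 1.5])
    def test_invariant_to_global_brightness_factor(self, spotted_egg, factor):
        egg, _, cfg = spotted_egg
        scaled = CalibratedEggImage(
            channels={ch: np.clip(a * factor, 0, 1) for ch, a in egg.channels.items()},
            mask=egg.mask,
            scale=egg.scale,
        )
        seg = segment_spots(correct_illumination(scaled))
        assert seg.n_spots == cfg.n_spots

    def test_component_areas_sum_to_spot_pixels(self, spotted_egg):
        egg, _, _ = spotted_egg
        seg = segment_spots(correct_illumination(egg))
        assert sum(seg.components) == seg.spot_mask.sum()


# ---------------------------------------------------------------------------
# Colour statistics and luminance histogram
# ---------------------------------------------------------------------------


class TestColourStats:
    def test_piecewise_constant_values_recovered(self):
        # large, well-resolved spots: anti-aliased rims are a negligible
        # fraction of the spot area, so means recover the render parameters
        cfg = ImageSynthConfig(
            n_spots=6,
            spot_radius_mm=1.4,
            spot_radius_sd_mm=0.0,
            min_separation_mm=0.8,
            seed=3,
        )
        egg, truth = render_egg_image(cfg)
        seg = segment_spots(correct_illumination(egg))
        out = colour_stats(egg, seg)
        # spot means then background means, order R,G,B,UV,brightness
        for i, ch in enumerate(("R", "G", "B", "UV", "LUM")):
            assert out[i] == pytest.approx(cfg.spot[ch], abs=0.01)
            assert out[5 + i] == pytest.approx(cfg.background[ch], abs=0.01)

    def test_spotless_falls_back_to_background(self):
        img = _uniform_egg(0.8)
        seg = segment_spots(img)
        out = colour_stats(img, seg)
        assert np.allclose(out[:5], out[5:])


class TestLuminanceHistogram:
    def test_uniform_value_fills_single_bin(self):
        img = _uniform_egg(0.55)
        h = luminance_histogram(img)
        assert h[5] == 1.0 and h.sum() == 1.0

    def test_two_level_image_splits_evenly(self):
        img = _uniform_egg(0.25)
        lum = img.channels["LUM"]
        half = np.zeros_like(lum, dtype=bool)
        half[:, : lum.shape[1] // 2] = True
        lum[half] = 0.75
        # make within-mask halves almost equal; compare against counting oracle
        h = luminance_histogram(img)
        vals = lum[img.mask]
        expect3 = np.mean((vals >= 0.2) & (vals < 0.3))
        expect8 = np.mean((vals >= 0.7) & (vals < 0.8))
        assert h[2] == pytest.approx(expect3, abs=1e-12)
        assert h[7] == pytest.approx(expect8, abs=1e-12)

    def test_matches_counting_oracle_on_render(self, spotted_egg):
        egg, _, _ = spotted_egg
        h = luminance_histogram(egg)
        vals = egg.channels["LUM"][egg.mask]
        oracle = np.array(
            [np.mean((vals >= i / 10) & (vals < (i + 1) / 10)) for i in range(9)]
            + [np.mean(vals >= 0.9)]
        )
        assert np.allclose(h, oracle)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Granularity spectrum
# ---------------------------------------------------------------------------


class TestGranularity:
    def test_uniform_image_all_zero(self):
        img = _uniform_egg(0.5)
        regions = partition_regions(img.mask)
        energy, skew = granularity_spectrum(img, regions)
        assert np.allclose(energy, 0.0, atol=1e-9)
        assert np.allclose(skew, 0.0)

    def test_negative_image_symmetry(self, spotted_egg):
        egg, _, _ = spotted_egg
        regions = partition_regions(egg.mask)
        e1, s1 = granularity_spectrum(egg, regions)
        neg = CalibratedEggImage(
            channels={ch: 1.0 - a for ch, a in egg.channels.items()},
            mask=egg.mask,
            scale=egg.scale,
        )
        e2, s2 = granularity_spectrum(neg, regions)
        assert np.allclose(e1, e2, atol=1e-9)
        assert np.allclose(s1, -s2, atol=1e-7)

    def test_dc_shift_invariance(self, spotted_egg):
        egg, _, _ = spotted_egg
        regions = partition_regions(egg.mask)
        e1, _ = granularity_spectrum(egg, regions)
        shifted = CalibratedEggImage(
            channels={ch: np.clip(a * 0.5 + 0.2, 0, 1) for ch, a in egg.channels.items()},
            mask=egg.mask,
            scale=egg.scale,
        )
        e2, _ = granularity_spectrum(shifted, regions)
        # affine a*0.5 + 0.2: band-pass removes the DC, halves the amplitude
        assert np.allclose(e1 * 0.5, e2, atol=1e-9)

    def test_sinusoid_energy_peaks_at_matching_scale(self):
        img = _uniform_egg(0.5, h=160, w=400)
        xs = np.where(img.mask.any(axis=0))[0]
        egg_len = xs[-1] - xs[0] + 1
        target = 3  # scale index
        period = pattern_scales()[target] * egg_len
        x = np.arange(img.mask.shape[1])
        wave = 0.5 + 0.25 * np.sin(2 * np.pi * x / period)
        img.channels["LUM"] = np.tile(wave, (img.mask.shape[0], 1))
        regions = partition_regions(img.mask)
        energy, _ = granularity_spectrum(img, regions)
        assert int(np.argmax(energy[:, 0])) == target

    def test_tiny_region_raises(self):
        img = _uniform_egg(0.5)
        regions = partition_regions(img.mask)
        regions.whole = img.mask
        regions.blunt = np.zeros_like(img.mask)
        with pytest.raises(ValueError):
            granularity_spectrum(img, regions)


# ---------------------------------------------------------------------------
# Spot metrics
# ---------------------------------------------------------------------------


class TestSpotMetrics:
    def test_spotless_all_zero(self):
        img = _uniform_egg(0.8)
        seg = segment_spots(img)
        regions = partition_regions(img.mask)
        out = spot_metrics(seg, regions, img.scale)
        assert np.allclose(out, 0.0)

    def test_dispersion_matches_zone_count_oracle(self):
        cfg = ImageSynthConfig(
            n_spots=15,
            spot_radius_mm=0.4,
            spot_radius_sd_mm=0.0,
            min_separation_mm=0.3,
            zone_weights=(1.0, 0.0, 0.0),  # all spots in the blunt third
            seed=7,
        )
        egg, _ = render_egg_image(cfg)
        seg = segment_spots(correct_illumination(egg))
        regions = partition_regions(egg.mask)
        out = spot_metrics(seg, regions, egg.scale)
        cov = []
        for name in ("blunt", "middle", "sharp"):
            reg = regions.regions()[name] & seg.analysis_mask
            cov.append(100.0 * (seg.spot_mask & reg).sum() / reg.sum())
        cov = np.array(cov)
        assert out[2] == pytest.approx(cov.mean())
        assert out[3] == pytest.approx(cov.std())
        assert out[4] == pytest.approx(100 * cov.std() / cov.mean())
        assert cov[0] > cov[1] + cov[2]  # maculation concentrated at blunt pole

    def test_equal_zone_coverage_gives_zero_cv(self):
        # symmetric synthetic segmentation: identical spot layout per third
        h, w = 60, 90
        mask = np.zeros((h, w), dtype=bool)
        mask[10:50, 3:87] = True
        spot = np.zeros_like(mask)
        for x0 in (10, 40, 70):  # same 8x8 spot in each third
            spot[20:28, x0 : x0 + 8] = True
        from eggid.imaging import SpotSegmentation

        seg = SpotSegmentation(
            spot_mask=spot, components=[64, 64, 64], analysis_mask=mask
        )
        regions = partition_regions(mask)
        out = spot_metrics(seg, regions, scale=10.0)
        assert out[3] == pytest.approx(0.0, abs=1e-9)
        assert out[4] == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Shape metrics
# ---------------------------------------------------------------------------


class TestShapeMetrics:
    def test_prolate_spheroid_closed_forms(self):
        cfg = ImageSynthConfig(length_mm=22.0, width_mm=14.0, n_spots=0, scale=15.0)
        egg, _ = render_egg_image(cfg)
        out = shape_metrics(egg.mask, egg.scale)
        a, b = 11.0, 7.0
        e = np.sqrt(1 - b * b / (a * a))
        vol = 4 / 3 * np.pi * a * b * b
        surf = 2 * np.pi * b * b * (1 + (a / (b * e)) * np.arcsin(e))
        assert out[0] == pytest.approx(22.0, rel=0.01)
        assert out[1] == pytest.approx(14.0, rel=0.01)
        assert out[2] == pytest.approx(vol, rel=0.01)
        assert out[3] == pytest.approx(surf, rel=0.01)
        assert out[4] < 0.005  # ellipse deviation ~ 0
        assert out[5] == pytest.approx(22 / 14, rel=0.01)

    def test_sphere(self):
        cfg = ImageSynthConfig(length_mm=20.0, width_mm=20.0, n_spots=0, scale=15.0)
        egg, _ = render_egg_image(cfg)
        out = shape_metrics(egg.mask, egg.scale)
        assert out[5] == pytest.approx(1.0, rel=0.01)
        assert out[2] == pytest.approx(4 / 3 * np.pi * 1000, rel=0.01)

    def test_mirror_invariance(self, spotted_egg):
        egg, _, _ = spotted_egg
        a = shape_metrics(egg.mask, egg.scale)
        b = shape_metrics(egg.mask[:, ::-1], egg.scale)
        assert np.allclose(a, b, rtol=1e-6)

    def test_pyriform_volume_matches_voxel_oracle(self):
        # asymmetric pear-shaped profile r(x) revolved about the x axis
        scale = 10.0
        L = 300
        x = np.arange(L)
        t = x / (L - 1)
        r = 60.0 * np.sqrt(np.clip(t * (1 - t), 0, None)) * (1.1 - 0.55 * t)
        h = 2 * int(r.max()) + 21
        mask = np.zeros((h, L + 20), dtype=bool)
        cy = h // 2
        for xi, ri in zip(x, r):
            if ri >= 0.5:
                lo, hi = int(np.ceil(cy - ri)), int(np.floor(cy + ri))
                mask[lo : hi + 1, xi + 10] = True
        out = shape_metrics(mask, scale)
        # voxel-counting oracle of the solid of revolution
        rr = mask.sum(axis=0) / 2.0
        zmax = int(rr.max()) + 2
        yy, zz = np.mgrid[-zmax:zmax + 1, -zmax:zmax + 1]
        voxels = sum(
            int((yy * yy + zz * zz <= ri * ri).sum()) for ri in rr if ri > 0
        )
        vol_oracle = voxels / scale**3
        assert out[2] == pytest.approx(vol_oracle, rel=0.02)

    def test_border_touching_mask_raises(self):
        mask = np.ones((50, 50), dtype=bool)
        with pytest.raises(ValueError, match="clipped"):
            shape_metrics(mask, 10.0)


# ---------------------------------------------------------------------------
# Regions, orientation, full extraction
# ---------------------------------------------------------------------------


class TestPartitionAndExtract:
    def test_partition_invariants_hold(self, spotted_egg):
        egg, _, _ = spotted_egg
        regions = partition_regions(egg.mask, "right")
        r = regions.regions()
        assert np.array_equal(r["blunt"] | r["middle"] | r["sharp"], egg.mask)

    def test_blunt_end_heuristic_on_asymmetric_mask(self):
        mask = np.zeros((60, 120), dtype=bool)
        y, x = np.mgrid[0:60, 0:120]
        mask[((x - 45) / 40.0) ** 2 + ((y - 30) / 25.0) ** 2 < 1] = True
        mask[((x - 80) / 30.0) ** 2 + ((y - 30) / 12.0) ** 2 < 1] = True
        assert detect_blunt_end(mask) == "left"

    def test_full_extraction_recovers_render_parameters(self, spotted_egg):
        egg, truth, cfg = spotted_egg
        fv = extract_features(egg)
        true_cov = 100.0 * truth.sum() / egg.mask.sum()
        assert fv.spot_metrics[1] == pytest.approx(true_cov, abs=2.0)
        assert fv.shape[0] == pytest.approx(cfg.length_mm, abs=1.5 / egg.scale)
        assert fv.shape[1] == pytest.approx(cfg.width_mm, abs=1.5 / egg.scale)
        assert abs(fv.luminance_bins.sum() - 1.0) < 1e-9
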