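"""Contrast, segmentation, background correction, conditional analysis."""

import numpy as np
import pytest

from chromemu.image import (
    background_corrected_mean,
    conditional_map,
    conditional_profile,
    detect_foci,
    image_contrast,
    radial_ring_profile,
    segment_nucleus,
    select_mid_section,
    subtract_local_background,
)


def cv_oracle(values):
    """Independent two-pass coefficient of variation."""
    m = sum(values) / len(values)
    var = sum((v - m) ** 2 for v in values) / (len(values) - 1)
    return var**0.5 / m


class TestImageContrast:
    def test_printed_formula_on_four_pixels(self):
        img = np.array([[1.0, 1.0], [3.0, 3.0]])
        res = image_contrast(img, np.ones((2, 2), bool))
        assert res.mean == pytest.approx(2.0)
        assert res.sd == pytest.approx(np.sqrt(4 / 3))
        assert res.c_dna == pytest.approx(np.sqrt(4 / 3) / 2, abs=1e-12)

    def test_constant_image_zero_contrast(self):
        res = image_contrast(np.full((5, 5), 7.0), np.ones((5, 5), bool))
        assert res.c_dna == 0.0

    def test_offset_correction_halves_at_equal_offset(self):
        img = np.array([[1.0, 1.0], [3.0, 3.0]])
        res = image_contrast(img, np.ones((2, 2), bool), offset=2.0)
        assert res.correction == pytest.approx(0.5)
        assert res.c_dna_corrected == pytest.approx(res.c_dna / 2, abs=1e-12)

    def test_zero_offset_identity_and_monotone_decrease(self, rng):
        img = rng.uniform(1, 5, (20, 20))
        mask = np.ones((20, 20), bool)
        base = image_contrast(img, mask, offset=0.0)
        assert base.c_dna_corrected == base.c_dna
        prev = base.c_dna_corrected
        for off in (0.5, 1.0, 2.0, 5.0):
            cur = image_contrast(img, mask, offset=off).c_dna_corrected
            assert cur < prev
            prev = cur

    def test_matches_independent_cv_oracle(self, rng):
        for _ in range(50):
            img = rng.uniform(0.5, 4.0, (8, 8))
            mask = rng.random((8, 8)) > 0.3
            if mask.sum() < 2:
                continue
            res = image_contrast(img, mask)
            assert res.c_dna == pytest.approx(cv_oracle(list(img[mask])),
                                              rel=1e-12)

    def test_outside_mask_pixels_ignored(self, rng):
        img = rng.uniform(1, 2, (10, 10))
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        res1 = image_contrast(img, mask)
        img2 = img.copy()
        img2[~mask] = 1e6
        res2 = image_contrast(img2, mask)
        assert res1.c_dna == res2.c_dna


class TestSegmentation:
    def test_bright_disc_eroded_by_structuring_radius(self):
        yy, xx = np.ogrid[0:128, 0:128]
        disc = (yy - 64) ** 2 + (xx - 64) ** 2 <= 50**2
        img = np.where(disc, 10.0, 1.0)
        m = segment_nucleus(img, erosion_radius=3).mask
        r_eff = np.sqrt(m.sum() / np.pi)
        assert r_eff == pytest.approx(47, abs=1.5)
        assert m[disc].all() or (m & ~disc).sum() == 0  # stays inside disc

    def test_ring_hole_is_filled(self):
        yy, xx = np.ogrid[0:64, 0:64]
        r2 = (yy - 32) ** 2 + (xx - 32) ** 2
        ring = (r2 <= 20**2) & (r2 >= 10**2)
        img = np.where(ring, 10.0, 1.0)
        m = segment_nucleus(img, erosion_radius=1).mask
        assert m[32, 32]  # center of the hole included after filling

    def test_constant_image_errors(self):
        with pytest.raises(ValueError):
            segment_nucleus(np.full((16, 16), 2.0))

    def test_empty_after_erosion_errors(self):
        img = np.zeros((16, 16))
        img[8, 8] = 10.0
        with pytest.raises(ValueError):
            segment_nucleus(img, erosion_radius=4)


class TestMidSection:
    def test_argmax_mean_slice(self):
        stack = np.stack([np.full((4, 4), v) for v in (1.0, 5.0, 2.0)])
        sec, z = select_mid_section(stack)
        assert z == 1
        assert np.array_equal(sec, stack[1])

    def test_tie_takes_lowest_index(self):
        stack = np.stack([np.full((4, 4), v) for v in (5.0, 5.0, 1.0)])
        _, z = select_mid_section(stack)
        assert z == 0

    def test_single_slice(self):
        sec, z = select_mid_section(np.ones((1, 4, 4)))
        assert z == 0

    def test_sphere_phantom_selects_equator(self):
        zz, yy, xx = np.ogrid[0:21, 0:41, 0:41]
        ball = (zz - 10) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 9**2
        _, z = select_mid_section(ball.astype(float))
        assert z == 10


class TestBackgroundCorrectedMean:
    def test_direct_means(self):
        img = np.full((40, 40), 2.0)
        mask = np.zeros((40, 40), bool)
        mask[15:25, 15:25] = True
        img[mask] = 5.0
        assert background_corrected_mean(img, mask, 3) == pytest.approx(3.0)

    def test_constant_channel_gives_zero(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        assert background_corrected_mean(np.full((20, 20), 4.0), mask) == 0.0

    def test_zero_surroundings_equals_in_mask_mean(self):
        img = np.zeros((30, 30))
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        img[mask] = 7.0
        assert background_corrected_mean(img, mask, 4) == pytest.approx(7.0)

    def test_mask_covering_everything_errors(self):
        with pytest.raises(ValueError):
            background_corrected_mean(np.ones((5, 5)), np.ones((5, 5), bool))


class TestConditionalAnalysis:
    def test_linear_relation_recovered(self, rng):
        B = rng.uniform(0, 1, (50, 50))
        A = 2 * B
        mask = np.ones((50, 50), bool)
        prof = conditional_profile(A, B, mask, bins=20)
        filled = prof.counts > 0
        half_bin = (prof.centers_raw[1] - prof.centers_raw[0]) / 2
        assert np.all(np.abs(prof.mean_a[filled]
                             - 2 * prof.centers_raw[filled]) <= 2 * half_bin)

    def test_constant_a_flat_profile(self, rng):
        B = rng.uniform(0, 1, (30, 30))
        prof = conditional_profile(np.full((30, 30), 5.0), B,
                                   np.ones((30, 30), bool))
        assert np.allclose(prof.mean_a[prof.counts > 0], 5.0)

    def test_empty_bins_flagged(self, rng):
        B = np.where(rng.random((30, 30)) > 0.5, 0.0, 1.0)  # only extremes
        prof = conditional_profile(B, B, np.ones((30, 30), bool), bins=10)
        assert prof.empty.any()

    def test_plane_recovered_in_2d_binning(self, rng):
        B = rng.uniform(0, 1, (60, 60))
        C = rng.uniform(0, 1, (60, 60))
        A = B + C
        m = conditional_map(A, B, C, np.ones((60, 60), bool), 10, 10)
        filled = m.counts > 0
        expect = m.centers_b[:, None] + m.centers_c[None, :]
        assert np.nanmax(np.abs(m.mean_a[filled] - expect[filled])) < 0.15

    def test_constant_a_constant_map(self, rng):
        B = rng.uniform(0, 1, (30, 30))
        C = rng.uniform(0, 1, (30, 30))
        m = conditional_map(np.full((30, 30), 2.0), B, C,
                            np.ones((30, 30), bool), 5, 5)
        assert np.allclose(m.mean_a[m.counts > 0], 2.0)


class TestLocalBackground:
    def test_constant_image_maps_to_zero(self):
        out = subtract_local_background(np.full((32, 32), 5.0), 100.0)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_impulse_center_positive(self):
        img = np.zeros((64, 64))
        img[32, 32] = 100.0
        out = subtract_local_background(img, 100.0)
        assert out[32, 32] > 0
        assert out[32, 32] < 100.0

    def test_slow_gradient_removed(self):
        img = np.linspace(0, 1, 64)[None, :] * np.ones((64, 1))
        out = subtract_local_background(img, 1000.0, sigma_um=2.38)
        assert np.abs(out[:, 16:-16]).max() < 0.05


class TestDetectFoci:
    @staticmethod
    def spot(shape, cy, cx, amp, sigma=2.0):
        yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
        return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))

    def test_two_spots_recovered_within_one_pixel(self):
        img = 0.1 + self.spot((64, 64), 20, 20, 10) + self.spot((64, 64), 44, 40, 8)
        cents = detect_foci(img, 2)
        found = sorted(cents)
        assert abs(found[0][0] - 20) <= 1 and abs(found[0][1] - 20) <= 1
        assert abs(found[1][0] - 44) <= 1 and abs(found[1][1] - 40) <= 1

    def test_single_spot_errors_when_two_requested(self):
        img = 0.1 + self.spot((64, 64), 30, 30, 10)
        with pytest.raises(ValueError):
            detect_foci(img, 2)

    def test_three_spots_keep_two_largest(self):
        img = (0.1 + self.spot((96, 96), 20, 20, 10, 4)
               + self.spot((96, 96), 70, 70, 10, 3)
               + self.spot((96, 96), 20, 70, 10, 1.5))
        cents = detect_foci(img, 2)
        ys = sorted(c[0] for c in cents)
        assert ys[0] == pytest.approx(20, abs=1.5)
        assert ys[1] == pytest.approx(70, abs=1.5)


class TestRadialRings:
    def test_first_ring_has_eight_pixels(self):
        prof = radial_ring_profile({"a": np.ones((21, 21))}, (10, 10), 5)
        assert prof.counts[0] == 1
        assert prof.counts[1] == 8

    def test_ring_r_has_8r_pixels_interior(self):
        prof = radial_ring_profile({"a": np.ones((41, 41))}, (20, 20), 10)
        assert np.array_equal(prof.counts[1:], 8 * np.arange(1, 11))

    def test_rings_tile_image_without_overlap(self):
        prof = radial_ring_profile({"a": np.ones((15, 15))}, (7, 7), 14)
        assert prof.counts.sum() == 15 * 15

    def test_constant_channel_flat_profile(self):
        prof = radial_ring_profile({"a": np.full((31, 31), 2.5)}, (15, 15), 8)
        assert np.allclose(prof.means["a"], 2.5)

    def test_border_clipping(self):
        prof = radial_ring_profile({"a": np.ones((11, 11))}, (0, 0), 3)
        assert prof.counts[1] == 3  # corner centroid keeps only 3 neighbors
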