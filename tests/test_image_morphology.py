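"""Unit and property tests for the image-analysis pipeline."""

import numpy as np
import pytest
from scipy import ndimage as scipy_ndimage

from contactprint import image_morphology as im

from conftest import (
    draw_disk,
    draw_ellipse,
    draw_half_disk,
    draw_rectangle,
    exhaustive_otsu,
)


class TestGrayscale:
    def test_single_channel_unchanged(self):
        img = np.random.default_rng(0).random((16, 16))
        assert np.array_equal(im.to_grayscale(img), img)

    def test_uniform_white_rgb(self):
        rgb = np.ones((8, 8, 3))
        assert np.allclose(im.to_grayscale(rgb), 1.0)

    def test_pure_red_luminance(self):
        rgb = np.zeros((4, 4, 3))
        rgb[..., 0] = 1.0
        assert np.allclose(im.to_grayscale(rgb), 0.299)

    def test_unsupported_channel_count(self):
        with pytest.raises(ValueError):
            im.to_grayscale(np.zeros((4, 4, 5)))


class TestBinarize:
    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = im.binarize(np.full((32, 32), 0.5))
        assert not mask.pixels.any()

    def test_two_level_image_otsu_recovers_construction(self):
        img = np.full((100, 100), 0.1)
        img[:10, :] = 0.9  # contiguous 10% block
        mask = im.binarize(img)
        assert mask.pixels.sum() == 1000

    def test_fixed_threshold_identity_on_binary_image(self):
        img = draw_disk().astype(float)
        mask = im.binarize(img, method="fixed", threshold=0.5)
        assert np.array_equal(mask.pixels, img.astype(bool))

    def test_fixed_requires_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            im.binarize(np.zeros((4, 4)), method="fixed")

    def test_largest_component_retained(self):
        img = np.full((64, 64), 0.1)
        img[10:30, 10:30] = 0.9  # 400 px blob
        img[50:53, 50:53] = 0.9  # 9 px speck
        mask = im.binarize(img)
        assert mask.pixels.sum() == 400
        assert not mask.pixels[50:53, 50:53].any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_otsu_equals_exhaustive_between_class_variance(self, seed):
        """The production threshold equals a naive 256-candidate search;
        component filtering matches an independent scipy labelling."""
        rng = np.random.default_rng(seed)
        img = np.where(draw_disk(radius=40 + 10 * seed), 0.9, 0.1)
        img = np.clip(img + rng.normal(0, 0.05, img.shape), 0, 1)
        t = exhaustive_otsu(img)
        fg = img > t
        labels, n = scipy_ndimage.label(fg)
        sizes = scipy_ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        oracle = labels == (1 + int(np.argmax(sizes)))
        mask = im.binarize(img)
        assert np.array_equal(mask.pixels, oracle)


class TestMeasureArea:
    def test_empty_mask(self):
        mask = im.BinaryMask(np.zeros((8, 8), bool), pixel_scale=0.5)
        assert im.measure_area(mask) == 0.0

    def test_pixel_counting(self):
        pix = np.zeros((8, 8), bool)
        pix[2:4, 2:4] = True
        assert im.measure_area(im.BinaryMask(pix, 0.5)) == pytest.approx(1.0)

    def test_disk_against_closed_form(self):
        mask = im.BinaryMask(draw_disk(radius=50), pixel_scale=0.02)
        assert im.measure_area(mask) == pytest.approx(np.pi * 1.0**2, rel=0.02)


class TestPrincipalOrientation:
    def test_disk_is_rotationally_ambiguous(self):
        orientation, ecc = im.principal_orientation(im.BinaryMask(draw_disk(), 1.0))
        assert ecc < 0.1
        assert orientation == 0.0

    def test_vertical_ellipse_zero_orientation(self):
        mask = im.BinaryMask(draw_ellipse(r_radius=100, c_radius=50), 1.0)
        orientation, ecc = im.principal_orientation(mask)
        assert abs(orientation) <= 1.0
        assert ecc > 0.5

    @pytest.mark.parametrize("angle", [-60.0, -30.0, 15.0, 30.0, 75.0])
    def test_rotated_ellipse_orientation_recovered(self, angle):
        mask = im.BinaryMask(
            draw_ellipse(r_radius=100, c_radius=50, rotation_deg=angle), 1.0
        )
        orientation, _ = im.principal_orientation(mask)
        assert orientation == pytest.approx(angle, abs=1.0)

    def test_too_few_pixels(self):
        pix = np.zeros((8, 8), bool)
        pix[3, 3] = True
        with pytest.raises(ValueError):
            im.principal_orientation(im.BinaryMask(pix, 1.0))


def _random_test_masks():
    cases = []
    for angle in (0.0, 20.0, 45.0, -35.0, 80.0):
        cases.append(("ellipse", draw_ellipse(r_radius=120, c_radius=55, rotation_deg=angle)))
        cases.append(("rect", draw_rectangle(height=220, width=90, rotation_deg=angle)))
    cases.append(("disk", draw_disk(shape=(512, 512), radius=90)))
    half = np.zeros((512, 512), bool)
    half[128:384, 128:384] = draw_half_disk(shape=(256, 256), radius=70)
    cases.append(("half", half))
    return cases


class TestAlignment:
    @pytest.mark.parametrize("name,pixels", _random_test_masks())
    def test_area_conserved_and_vertical(self, name, pixels):
        """Alignment changes area by at most 2% and leaves the longest axis
        within 1 degree of vertical for unambiguous shapes."""
        mask = im.BinaryMask(pixels, 0.02)
        aligned = im.align_mask(mask)
        a_in, a_out = im.measure_area(mask), im.measure_area(aligned)
        assert abs(a_out - a_in) / a_in <= 0.02
        orientation, ecc = im.principal_orientation(aligned)
        if ecc >= 0.1:
            assert abs(orientation) <= 1.0

    @pytest.mark.parametrize("name,pixels", _random_test_masks())
    def test_idempotent_within_one_percent(self, name, pixels):
        mask = im.BinaryMask(pixels, 0.02)
        once = im.align_mask(mask)
        twice = im.align_mask(once, canvas=once.pixels.shape)
        changed = np.logical_xor(once.pixels, twice.pixels).sum()
        assert changed <= 0.01 * once.pixels.sum()

    def test_offset_circle_is_recentred(self):
        pixels = draw_disk(shape=(256, 256), center=(60, 70), radius=40)
        aligned = im.align_mask(im.BinaryMask(pixels, 1.0), canvas=(256, 256))
        cr, cc = scipy_ndimage.center_of_mass(aligned.pixels)
        assert abs(cr - 127.5) <= 1.0 and abs(cc - 127.5) <= 1.0
        assert aligned.pixels.sum() == pytest.approx(pixels.sum(), rel=0.02)

    def test_centred_vertical_ellipse_nearly_unchanged(self):
        pixels = draw_ellipse(shape=(511, 511), r_radius=100, c_radius=50)
        mask = im.BinaryMask(pixels, 1.0)
        aligned = im.align_mask(mask, canvas=(511, 511))
        disagree = np.logical_xor(aligned.pixels, pixels).sum()
        assert disagree <= 0.01 * pixels.sum()

    def test_canvas_too_small(self):
        with pytest.raises(ValueError, match="canvas"):
            im.align_mask(im.BinaryMask(draw_disk(radius=60), 1.0), canvas=(32, 32))


class TestAverageMorphology:
    def test_identical_replicates(self):
        masks = [im.BinaryMask(draw_disk(), 1.0) for _ in range(6)]
        prof = im.average_morphology(masks)
        assert set(np.unique(prof.occupancy)) <= {0.0, 1.0}
        assert prof.consensus_mask.pixels.sum() == pytest.approx(
            masks[0].pixels.sum(), rel=0.02
        )
        assert prof.n_replicates == 6

    def test_majority_tie_rule(self):
        """A pixel covered by exactly half the replicates has occupancy 0.5
        and sits inside the consensus; 2 of 6 stays outside."""
        base = draw_disk(shape=(64, 64), radius=20)
        extra_a = base.copy()
        extra_a[32 + 22, 32] = True  # covered by 3 of 6
        extra_b = base.copy()
        extra_b[32, 32 + 22] = True  # covered by 2 of 6
        masks = [im.BinaryMask(p, 1.0) for p in
                 [extra_a, extra_a, extra_a, extra_b, extra_b, base]]
        prof = im.average_morphology(masks, canvas=(64, 64))
        # alignment leaves these single-component disks in place (ecc < 0.1)
        r_a = np.argwhere(prof.occupancy == 0.5)
        assert len(r_a) >= 1
        assert prof.consensus_mask.pixels[tuple(r_a[0])]
        near_third = np.isclose(prof.occupancy, 2 / 6)
        assert near_third.any()
        assert not prof.consensus_mask.pixels[near_third].any()

    def test_mismatched_scales_rejected(self):
        masks = [im.BinaryMask(draw_disk(), 1.0), im.BinaryMask(draw_disk(), 0.5)]
        with pytest.raises(ValueError, match="scale"):
            im.average_morphology(masks)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            im.average_morphology([])

    def test_consensus_inside_union(self):
        rng = np.random.default_rng(0)
        masks = []
        for _ in range(4):
            c = (128 + rng.integers(-4, 5), 128 + rng.integers(-4, 5))
            masks.append(im.BinaryMask(draw_disk(center=c, radius=40), 1.0))
        prof = im.average_morphology(masks)
        aligned_union = prof.occupancy > 0
        assert not (prof.consensus_mask.pixels & ~aligned_union).any()


class TestClassification:
    def test_rectangle_is_t1(self):
        desc = im.compute_descriptors(
            im.BinaryMask(draw_rectangle(height=200, width=80, rotation_deg=10), 1.0)
        )
        assert desc.rectangularity > 0.9
        assert im.classify_morphology(desc) == "T1"

    def test_disk_is_t3(self):
        desc = im.compute_descriptors(im.BinaryMask(draw_disk(), 1.0))
        assert desc.eccentricity < 0.1
        assert im.classify_morphology(desc) == "T3"

    def test_half_disk_is_t2(self):
        desc = im.compute_descriptors(im.BinaryMask(draw_half_disk(), 1.0))
        assert desc.axial_asymmetry > 0.15
        assert im.classify_morphology(desc) == "T2"

    def test_ellipse_is_t4(self):
        desc = im.compute_descriptors(
            im.BinaryMask(draw_ellipse(r_radius=110, c_radius=60, rotation_deg=25), 1.0)
        )
        assert im.classify_morphology(desc) == "T4"

    @pytest.mark.parametrize("name,pixels", _random_test_masks())
    def test_exactly_one_class(self, name, pixels):
        desc = im.compute_descriptors(im.BinaryMask(pixels, 1.0))
        assert im.classify_morphology(desc) in {"T1", "T2", "T3", "T4"}


class TestRasterisedShapeAreas:
    """Measured pixel areas of analytic shapes match closed forms within 2%."""

    @pytest.mark.parametrize(
        "pixels,analytic",
        [
            (draw_disk(shape=(512, 512), radius=80), np.pi * 80**2),
            (draw_ellipse(r_radius=120, c_radius=55), np.pi * 120 * 55),
            (draw_rectangle(height=220, width=90), 220 * 90),
            (draw_half_disk(shape=(512, 512), radius=100), np.pi * 100**2 / 2),
        ],
    )
    def test_area_matches_closed_form(self, pixels, analytic):
        mask = im.BinaryMask(pixels, 1.0)
        assert im.measure_area(mask) == pytest.approx(analytic, rel=0.02)
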