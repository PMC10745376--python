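import numpy as np
import pytest
from scipy import ndimage as ndi

from angiosprout import SyntheticChipSpec, generate_chip
from angiosprout.chip_geometry import (
    ChipMasks,
    GeometryError,
    GuideDetectionError,
    GuideDetectionParams,
    build_chip_masks,
    compute_reference_line,
    derive_ecm_mask,
    detect_guides,
    fill_top_guide,
)

PARAMS = GuideDetectionParams(threshold_lo=500, area_min_px=500, area_max_px=10_000)


class TestDetectGuides:
    def test_two_bar_centroids(self, two_bar_image):
        top, bottom = detect_guides(two_bar_image, PARAMS)
        cy_top = ndi.center_of_mass(top)[0]
        cy_bot = ndi.center_of_mass(bottom)[0]
        assert abs(cy_top - 109.5) <= 1.0
        assert abs(cy_bot - 309.5) <= 1.0

    def test_speckles_cleared_by_shrink(self, two_bar_image):
        """Small bright artefacts are removed by the 5 px shrink and do not
        change the detected guide masks."""
        clean_top, clean_bot = detect_guides(two_bar_image, PARAMS)
        noisy = two_bar_image.copy()
        rng = np.random.default_rng(1)
        for _ in range(20):
            y, x = rng.integers(130, 290), rng.integers(5, 395)
            noisy[y : y + 4, x : x + 4] = 1000  # 16 px < 25 px speckles
        top, bottom = detect_guides(noisy, PARAMS)
        np.testing.assert_array_equal(top, clean_top)
        np.testing.assert_array_equal(bottom, clean_bot)

    def test_blank_image_fails_at_threshold_stage(self):
        with pytest.raises(GuideDetectionError, match="threshold"):
            detect_guides(np.zeros((100, 100)), PARAMS)

    def test_single_bar_fails_area_stage(self):
        img = np.zeros((200, 200), dtype=np.uint16)
        img[50:70, :] = 1000
        with pytest.raises(GuideDetectionError, match="area-filter"):
            detect_guides(img, PARAMS)

    def test_erosion_does_not_bias_guide_extent(self, two_bar_image):
        """Survivor restoration undoes the artefact-clearing erosion, so the
        detected bar spans its full drawn footprint."""
        top, _ = detect_guides(two_bar_image, PARAMS)
        assert top[100:120, 50:350].all()


class TestFillTopGuide:
    def test_closes_hole(self):
        guide = np.zeros((60, 200), dtype=bool)
        guide[20:40, :] = True
        guide[27:33, 90:96] = False  # 6 px hole
        params = GuideDetectionParams(fill_radius_px=5)
        filled = fill_top_guide(guide, params)
        n_holes_before = ndi.label(~guide)[1] - 1  # minus outer background
        n_holes_after = ndi.label(~filled)[1] - 1
        assert n_holes_before == 2  # hole splits complement into 3 regions - 1
        assert n_holes_after <= 1
        assert filled[27:33, 90:96].all()
        assert (filled | guide).sum() == filled.sum()  # superset of input

    def test_zero_radius_is_identity(self):
        guide = np.zeros((30, 50), dtype=bool)
        guide[10:20, :] = True
        out = fill_top_guide(guide, GuideDetectionParams(fill_radius_px=0))
        np.testing.assert_array_equal(out, guide)

    def test_solid_bar_unchanged(self):
        guide = np.zeros((30, 50), dtype=bool)
        guide[10:20, :] = True
        out = fill_top_guide(guide, GuideDetectionParams(fill_radius_px=5))
        np.testing.assert_array_equal(out, guide)


class TestDeriveEcmMask:
    def test_full_width_guide_splits_rows(self):
        guide = np.zeros((100, 100), dtype=bool)
        guide[40:51, :] = True
        tube, ecm = derive_ecm_mask(guide, (100, 100))
        assert tube[:40].all() and not tube[40:].any()
        assert ecm[51:].all() and not ecm[:51].any()

    def test_bottom_guide_clips_ecm(self):
        guide = np.zeros((100, 100), dtype=bool)
        guide[40:51, :] = True
        bottom = np.zeros((100, 100), dtype=bool)
        bottom[80:90, :] = True
        _, ecm = derive_ecm_mask(guide, (100, 100), bottom_guide=bottom)
        assert ecm[51:80].all()
        assert not ecm[80:].any()

    def test_gap_in_guide_is_geometry_error(self):
        guide = np.zeros((100, 100), dtype=bool)
        guide[40:51, :60] = True  # does not span width
        with pytest.raises(GeometryError, match="width"):
            derive_ecm_mask(guide, (100, 100))

    def test_synthetic_chip_gel_coverage(self, default_chip, default_masks):
        _, truth = default_chip
        h, w = truth.top_guide_mask.shape
        rows = np.arange(h)[:, None]
        if_row = truth.interface_row_px(np.arange(w), 2.0)
        gel_true = (rows >= if_row[None, :]) & (rows < if_row[None, :] + 120)
        tube_true = rows < (if_row[None, :] - 20)
        coverage = (default_masks.ecm_mask & gel_true).sum() / gel_true.sum()
        leakage = (default_masks.ecm_mask & tube_true).sum() / tube_true.sum()
        assert coverage >= 0.99
        assert leakage < 0.01


class TestReferenceLine:
    def test_set_algebra_example(self):
        guide = np.zeros((100, 100), dtype=bool)
        guide[40:51, :] = True
        ecm = np.zeros((100, 100), dtype=bool)
        ecm[51:, :] = True
        params = GuideDetectionParams(ref_dilation_px=3)
        line, ref_y = compute_reference_line(guide, ecm, params)
        assert ref_y == 51
        assert line[51:54, :].all()
        assert not line[54:].any() and not line[:51].any()

    def test_translation_equivariance(self, two_bar_image, config):
        masks = build_chip_masks(two_bar_image, PARAMS)
        shifted = np.zeros_like(two_bar_image)
        shifted[17:] = two_bar_image[:-17]
        masks2 = build_chip_masks(shifted, PARAMS)
        assert masks2.reference_y_px == masks.reference_y_px + 17
        np.testing.assert_array_equal(
            masks2.ecm_mask[17:], masks.ecm_mask[:-17]
        )

    def test_empty_intersection_is_geometry_error(self):
        guide = np.zeros((100, 100), dtype=bool)
        guide[10:20, :] = True
        ecm = np.zeros((100, 100), dtype=bool)
        ecm[80:, :] = True  # far from the guide
        with pytest.raises(GeometryError):
            compute_reference_line(guide, ecm, GuideDetectionParams(ref_dilation_px=3))

    @pytest.mark.parametrize("tilt", [1.0, -1.0])
    def test_line_tracks_tilted_interface(self, tilt, config):
        channels, truth = generate_chip(SyntheticChipSpec(seed=3, tilt_deg=tilt))
        masks = build_chip_masks(channels["nuclear"].image, config.geometry)
        line = masks.reference_line
        cols = np.nonzero(line.any(axis=0))[0]
        top_rows = np.argmax(line[:, cols], axis=0)
        true_rows = truth.interface_row_px(cols, 2.0)
        assert np.abs(top_rows - true_rows).max() <= 2.0


class TestFullGeometry:
    def test_masks_are_pairwise_disjoint(self, default_masks):
        m = default_masks
        assert not (m.tube_mask & m.ecm_mask).any()
        assert not (m.top_guide & m.ecm_mask).any()
        assert not (m.top_guide & m.tube_mask).any()
        assert not (m.top_guide & m.bottom_guide).any()

    def test_reference_line_invariants(self, default_masks):
        m = default_masks
        assert (m.reference_line & ~m.ecm_mask).sum() == 0  # line inside gel
        min_line_y = np.nonzero(m.reference_line.any(axis=1))[0].min()
        ecm_rows = np.nonzero(m.ecm_mask.any(axis=1))[0]
        assert (ecm_rows >= min_line_y).all()

    def test_determinism_bit_identical(self, default_chip, config):
        channels, _ = default_chip
        a = build_chip_masks(channels["nuclear"].image, config.geometry)
        b = build_chip_masks(channels["nuclear"].image, config.geometry)
        np.testing.assert_array_equal(a.ecm_mask, b.ecm_mask)
        np.testing.assert_array_equal(a.reference_line, b.reference_line)
        assert a.reference_y_px == b.reference_y_px
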