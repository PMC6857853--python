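"""FOV estimation, circumcircle, thresholding, watershed, ROI extraction."""

import math
import warnings

import numpy as np
import pytest

from oralcyto.segmentation import (CellMask, CircleFOV, DegenerateCircleError,
                                   FieldImage, FOVNotDetectedError,
                                   circumcircle, clear_background,
                                   extract_cell_rois, find_fov_edge_points,
                                   segment_field, split_clumps,
                                   threshold_cell_mass, trim_to_fov)
from oralcyto.synthetic import generate_field_image
from conftest import match_count, small_scene


def _disc_image(h=200, w=200, cx=100, cy=100, r=30, bg=230, fg=80):
    px = np.full((h, w, 3), bg, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    px[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = fg
    return px


class TestEdgePoints:
    def test_points_land_on_true_circle(self, default_field):
        img, gt = default_field
        pts = find_fov_edge_points(img)
        for x, y in pts:
            d = math.hypot(x - gt.fov.cx, y - gt.fov.cy)
            assert abs(d - gt.fov.radius) < 2.0

    def test_uniform_black_image_raises(self):
        img = FieldImage(pixels=np.zeros((64, 64, 3), dtype=np.uint8))
        with pytest.raises(FOVNotDetectedError):
            find_fov_edge_points(img)

    def test_full_frame_bright_flags_low_confidence(self):
        img = FieldImage(pixels=np.full((64, 64, 3), 220, dtype=np.uint8))
        pts = find_fov_edge_points(img)
        assert pts.low_confidence
        assert len(pts) == 3


class TestCircumcircle:
    @pytest.mark.parametrize("pts,center,radius", [
        (((0, 1), (1, 0), (0, -1)), (0.0, 0.0), 1.0),
        (((1, 1), (4, 1), (1, 5)), (2.5, 3.0), 2.5),
    ])
    def test_known_circles(self, pts, center, radius):
        fov = circumcircle(*pts)
        assert fov.cx == pytest.approx(center[0])
        assert fov.cy == pytest.approx(center[1])
        assert fov.radius == pytest.approx(radius)

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateCircleError):
            circumcircle((0, 0), (1, 1), (2, 2))

    def test_recovery_on_random_circles(self):
        """1000 random circles, 3 sampled boundary points each: centre and
        radius recovered to < 1e-6 relative error."""
        rng = np.random.default_rng(17)
        for _ in range(1000):
            cx, cy = rng.uniform(-1e3, 1e3, 2)
            r = rng.uniform(1.0, 1e3)
            angs = rng.uniform(0, 2 * math.pi, 3)
            # keep the points from being nearly collinear
            while np.min(np.abs(np.diff(np.sort(angs % math.pi)))) < 0.05:
                angs = rng.uniform(0, 2 * math.pi, 3)
            pts = [(cx + r * math.cos(a), cy + r * math.sin(a)) for a in angs]
            fov = circumcircle(*pts)
            err = max(abs(fov.cx - cx), abs(fov.cy - cy), abs(fov.radius - r))
            assert err / r < 1e-6


class TestTrim:
    def test_everything_outside_circle_zeroed(self, default_field):
        img, gt = default_field
        out = trim_to_fov(img, gt.fov)
        ys, xs = np.nonzero(out.pixels.sum(axis=2))
        d = np.hypot(xs - out.fov.cx, ys - out.fov.cy)
        assert d.max() <= gt.fov.radius + 1.0

    def test_circle_covering_image_is_identity_crop(self):
        px = np.full((50, 60, 3), 200, dtype=np.uint8)
        img = FieldImage(pixels=px)
        out = trim_to_fov(img, CircleFOV(30, 25, 500))
        assert np.array_equal(out.pixels, px)

    def test_tiny_circle_gives_tiny_crop(self):
        img = FieldImage(pixels=np.full((50, 50, 3), 200, dtype=np.uint8))
        out = trim_to_fov(img, CircleFOV(25, 25, 1))
        assert out.pixels.shape[0] <= 4 and out.pixels.shape[1] <= 4
        assert np.count_nonzero(out.pixels.sum(axis=2)) <= 5

    def test_circle_outside_image_raises(self):
        img = FieldImage(pixels=np.zeros((50, 50, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            trim_to_fov(img, CircleFOV(500, 500, 10))


class TestThreshold:
    def test_dark_disc_area_recovered(self):
        img = FieldImage(pixels=_disc_image(r=30))
        mask = threshold_cell_mass(img)
        area = int(mask.data.sum())
        assert abs(area - math.pi * 30 ** 2) / (math.pi * 30 ** 2) < 0.10

    def test_uniform_field_yields_empty_mask(self):
        img = FieldImage(pixels=np.full((100, 100, 3), 210, dtype=np.uint8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = threshold_cell_mass(img)
        assert not mask.data.any()

    def test_only_green_channel_matters(self):
        """Permuting red and blue leaves the mask unchanged."""
        px = _disc_image()
        rng = np.random.default_rng(0)
        px[:, :, 0] = rng.integers(0, 255, px.shape[:2], dtype=np.uint8)
        px[:, :, 2] = rng.integers(0, 255, px.shape[:2], dtype=np.uint8)
        m1 = threshold_cell_mass(FieldImage(pixels=px))
        swapped = px[:, :, ::-1].copy()
        m2 = threshold_cell_mass(FieldImage(pixels=swapped))
        assert np.array_equal(m1.data, m2.data)


class TestClearBackground:
    def test_background_pixels_zeroed(self):
        img = FieldImage(pixels=_disc_image(r=20))
        mask = threshold_cell_mass(img)
        kept, cleared = clear_background(mask, img)
        assert np.all(cleared.pixels[~kept.data] == 0)
        assert cleared.pixels[kept.data].any()

    def test_empty_mask_blanks_image(self):
        img = FieldImage(pixels=_disc_image(r=20))
        empty = CellMask(np.zeros((200, 200), dtype=bool))
        _, cleared = clear_background(empty, img)
        assert not cleared.pixels.any()

    def test_speck_below_default_size_removed(self):
        data = np.zeros((50, 50), dtype=bool)
        data[10:12, 10:12] = True  # 4 px^2 speck
        data[30:40, 30:40] = True  # 100 px^2 keeper
        img = FieldImage(pixels=np.zeros((50, 50, 3), dtype=np.uint8))
        kept, _ = clear_background(CellMask(data), img)
        assert not kept.data[10, 10]
        assert kept.data[35, 35]


class TestWatershed:
    @staticmethod
    def _two_discs(sep=45):
        data = np.zeros((120, 160), dtype=bool)
        yy, xx = np.mgrid[0:120, 0:160]
        data |= (xx - 60) ** 2 + (yy - 60) ** 2 <= 30 ** 2
        data |= (xx - 60 - sep) ** 2 + (yy - 60) ** 2 <= 30 ** 2
        return data

    def test_overlapping_discs_split_in_two(self):
        from skimage.measure import label

        mask = CellMask(self._two_discs(sep=45))  # 1.5 radii apart
        assert label(mask.data).max() == 1
        out = split_clumps(mask)
        assert label(out.data).max() == 2

    def test_isolated_discs_untouched_in_count(self):
        from skimage.measure import label

        data = self._two_discs(sep=90)  # disjoint
        out = split_clumps(CellMask(data))
        assert label(out.data).max() == label(data).max()

    def test_empty_mask_passthrough(self):
        out = split_clumps(CellMask(np.zeros((20, 20), dtype=bool)))
        assert not out.data.any()

    def test_never_creates_foreground_outside_input(self):
        data = self._two_discs(sep=45)
        out = split_clumps(CellMask(data))
        assert not (out.data & ~data).any()

    def test_component_count_never_decreases(self):
        from skimage.measure import label

        rng = np.random.default_rng(8)
        for _ in range(5):
            data = np.zeros((100, 100), dtype=bool)
            yy, xx = np.mgrid[0:100, 0:100]
            for _ in range(rng.integers(1, 5)):
                cx, cy = rng.uniform(15, 85, 2)
                r = rng.uniform(6, 18)
                data |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
            before = label(data).max()
            after = label(split_clumps(CellMask(data)).data).max()
            assert after >= before


class TestExtractROIs:
    def test_component_count_and_ordering(self):
        data = np.zeros((100, 100), dtype=bool)
        data[10:20, 60:70] = True
        data[40:50, 10:20] = True
        data[70:80, 40:50] = True
        img = FieldImage(pixels=np.full((100, 100, 3), 120, dtype=np.uint8))
        rois = extract_cell_rois(CellMask(data), img)
        assert len(rois) == 3
        assert [(r.y0, r.x0) for r in rois] == [(10, 60), (40, 10), (70, 40)]
        assert [r.roi_id for r in rois] == [0, 1, 2]

    def test_rectangle_aspect_ratio(self):
        data = np.zeros((60, 60), dtype=bool)
        data[20:30, 10:30] = True  # 10 x 20 rectangle
        img = FieldImage(pixels=np.zeros((60, 60, 3), dtype=np.uint8))
        (roi,) = extract_cell_rois(CellMask(data), img)
        assert roi.aspect_ratio == pytest.approx(2.0, rel=0.05)

    def test_empty_mask_gives_empty_list(self):
        img = FieldImage(pixels=np.zeros((30, 30, 3), dtype=np.uint8))
        assert extract_cell_rois(CellMask(np.zeros((30, 30), bool)), img) == []

    def test_channel_means_computed_over_mask(self):
        px = np.zeros((40, 40, 3), dtype=np.uint8)
        px[:, :, 0] = 50
        px[:, :, 1] = 100
        px[:, :, 2] = 150
        data = np.zeros((40, 40), dtype=bool)
        data[10:20, 10:20] = True
        (roi,) = extract_cell_rois(CellMask(data), FieldImage(pixels=px))
        assert roi.channel_means == pytest.approx((50.0, 100.0, 150.0))


class TestSegmentField:
    def test_all_cells_recovered_with_matching_centroids(self, segmented_field):
        img, gt, rois = segmented_field
        assert len(rois) == len(gt.cells)
        assert match_count(gt.cells, rois) == len(gt.cells)

    def test_empty_field_yields_no_rois(self):
        img, _ = generate_field_image(small_scene(n_cells=0, seed=2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert segment_field(img) == []

    def test_all_rois_inside_fov(self, segmented_field):
        _, gt, rois = segmented_field
        for r in rois:
            for x, y in ((r.x0, r.y0), (r.x1, r.y1)):
                assert math.hypot(x - gt.fov.cx, y - gt.fov.cy) \
                    <= gt.fov.radius + 2.0

    def test_stage_name_propagates_on_failure(self):
        img = FieldImage(pixels=np.zeros((64, 64, 3), dtype=np.uint8))
        with pytest.raises(FOVNotDetectedError, match="find_fov_edge_points"):
            segment_field(img)
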