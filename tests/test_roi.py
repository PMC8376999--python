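"""Segmentation, de-skew, landmark and ROI-formula behavior."""

import numpy as np
import pytest

from finprint import roi as R
from finprint import synthetic as syn
from finprint.types import FishObject


def _object_from_mask(mask, gray=None):
    mask = np.asarray(mask, bool)
    return FishObject(mask=mask,
                      gray=(np.full(mask.shape, 150.0)
                            if gray is None else np.asarray(gray, float)))


class TestSegmentBackground:
    def test_all_green_frame_is_background(self):
        img = np.zeros((20, 30, 3), np.uint8)
        img[:] = syn.BACKGROUND_RGB
        assert R.segment_background(img).all()

    def test_all_black_frame_has_no_background(self):
        img = np.zeros((20, 30, 3), np.uint8)
        assert not R.segment_background(img).any()

    def test_fish_pixels_excluded_on_render(self, cohort_products):
        rec = cohort_products[0]
        bg = R.segment_background(rec["image"].image)
        fish_mask = rec["image"].truth["mask"]
        assert (bg & fish_mask).sum() / fish_mask.sum() < 0.01


class TestLocateFish:
    def test_render_component_matches_truth_silhouette(self, cohort_products):
        rec = cohort_products[0]
        bg = R.segment_background(rec["image"].image)
        obj = R.locate_fish(bg, rec["image"].image)
        gt = rec["image"].truth["mask"]
        ys, xs = np.nonzero(gt)
        det = np.zeros_like(gt)
        inv = np.linalg.inv(obj.transform)
        # place the cropped mask back on the canvas via the stored offset
        oy, ox = int(round(inv[1, 2])), int(round(inv[0, 2]))
        det[oy:oy + obj.mask.shape[0], ox:ox + obj.mask.shape[1]] = obj.mask
        iou = (det & gt).sum() / (det | gt).sum()
        assert iou >= 0.95

    def test_larger_of_two_blobs_wins(self):
        bg = np.ones((40, 60), bool)
        bg[5:10, 5:10] = False      # 25 px blob
        bg[20:35, 20:50] = False    # 450 px blob
        obj = R.locate_fish(bg)
        assert obj.mask.shape == (15, 30)

    def test_empty_foreground_raises(self):
        with pytest.raises(R.NoFishError):
            R.locate_fish(np.ones((10, 10), bool))


class TestDeskew:
    def test_rotated_render_comes_back_horizontal(self, small_cohort):
        fi = small_cohort.render(0)
        bg = R.segment_background(fi.image)
        obj = R.deskew(R.locate_fish(bg, fi.image))
        assert abs(R.mask_orientation_deg(obj.mask)) <= 1.0

    def test_already_horizontal_nearly_unchanged(self):
        mask = np.zeros((60, 200), bool)
        mask[20:40, 10:190] = True
        gray = np.full(mask.shape, 150.0)
        gray[25:35, 15:25] = 5.0  # eye, head-left
        obj = R.deskew(_object_from_mask(mask, gray))
        assert abs(obj.orientation_applied_deg) < 1e-6
        assert obj.mask.sum() == mask.sum()

    def test_head_right_input_flipped_head_left(self, small_cohort):
        fi = small_cohort.render(0)
        flipped = fi.image[:, ::-1].copy()
        bg = R.segment_background(flipped)
        obj = R.deskew(R.locate_fish(bg, flipped))
        dark_x = np.nonzero((obj.gray < 20) & obj.mask)[1]
        assert np.median(dark_x) < obj.mask.shape[1] / 2


class TestFindNarrowest:
    def test_direct_argmin_on_synthetic_widths(self):
        # posterior-half widths [10, 8, 3, 9] -> the 3-wide column wins
        mask = np.zeros((20, 8), bool)
        widths = [10, 10, 10, 10, 10, 8, 3, 9]
        for x, w in enumerate(widths):
            mask[10 - w // 2:10 - w // 2 + w, x] = True
        obj = _object_from_mask(mask)
        assert R.find_narrowest(obj, tail_margin=0.0) == 6

    def test_rectangle_tie_breaks_rightmost(self):
        mask = np.ones((10, 40), bool)
        assert R.find_narrowest(_object_from_mask(mask), tail_margin=0.0) == 39

    def test_waist_recovered_on_render(self, cohort_products):
        for rec in cohort_products[:6]:
            obj = rec["obj"]
            gt_np = obj.to_object(
                np.array(rec["image"].truth["landmarks_canvas"]["NP"]))[0]
            assert abs(rec["roi"].landmarks.NP - gt_np[0]) <= 4


class TestFindUpperFin:
    def test_two_symmetric_ramps_intersect_exactly(self):
        # top border: flat at y=30 left of x0=40, rising slope 0.5 after
        mask = np.zeros((100, 81), bool)
        for x in range(81):
            y_top = 30 + round(0.5 * max(x - 40, 0))
            mask[y_top:90, x] = True
        obj = _object_from_mask(mask)
        ux, uy = R.find_upper_fin(obj, length_px=80)
        assert abs(ux - 40) <= 1.5
        assert abs(uy - 30) <= 1.0

    def test_flat_border_uses_fallback(self):
        mask = np.zeros((30, 81), bool)
        mask[10:25, :] = True
        obj = _object_from_mask(mask)
        ux, uy = R.find_upper_fin(obj, length_px=80)
        assert uy == 10.0

    def test_fin_base_recovered_on_render(self, cohort_products):
        for rec in cohort_products[:6]:
            obj = rec["obj"]
            gt_up = obj.to_object(
                np.array(rec["image"].truth["landmarks_canvas"]["UP"]))[0]
            det = np.array(rec["roi"].landmarks.UP)
            assert np.hypot(*(det - gt_up)) <= 4.0


class TestFindEye:
    def test_centroid_of_dark_disk(self):
        gray = np.full((200, 400), 120.0)
        yy, xx = np.mgrid[0:200, 0:400]
        gray[np.hypot(xx - 80, yy - 120) < 8] = 10.0
        obj = _object_from_mask(np.ones_like(gray, bool), gray)
        ep = R.find_eye(obj, UP=(400.0, 0.0))
        assert np.hypot(ep[0] - 80, ep[1] - 120) <= 1.0

    def test_bright_head_raises(self):
        obj = _object_from_mask(np.ones((50, 90), bool),
                                np.full((50, 90), 200.0))
        with pytest.raises(R.EyeNotFoundError):
            R.find_eye(obj, UP=(90.0, 0.0))

    def test_two_dark_blobs_give_union_centroid(self):
        gray = np.full((60, 120), 150.0)
        gray[10:14, 10:14] = 5.0
        gray[30:34, 20:24] = 5.0
        obj = _object_from_mask(np.ones_like(gray, bool), gray)
        ep = R.find_eye(obj, UP=(120.0, 0.0))
        assert ep == (pytest.approx(16.5), pytest.approx(21.5))


class TestFindBelly:
    def test_bottom_extent_and_invariant(self, cohort_products):
        for rec in cohort_products[:3]:
            lm = rec["roi"].landmarks
            assert lm.BP[0] == lm.UP[0]
            assert lm.BP[1] > lm.UP[1]
            gt_bp = rec["obj"].to_object(
                np.array(rec["image"].truth["landmarks_canvas"]["BP"]))[0]
            assert abs(lm.BP[1] - gt_bp[1]) <= 5.0


class TestExtractROI:
    def test_formula_example(self):
        obj = _object_from_mask(np.ones((500, 600), bool))
        _crop, (x0, x1, y0, y1) = R.extract_roi(
            obj, EP=(120, 140), UP=(480, 60), BP=(480, 420))
        assert (x0, x1, y0, y1) == (120, 480, 78, 210)

    def test_formula_zero_up(self):
        obj = _object_from_mask(np.ones((500, 600), bool))
        _crop, (_x0, _x1, y0, y1) = R.extract_roi(
            obj, EP=(10, 0), UP=(400, 0), BP=(400, 400))
        assert (y0, y1) == (20, 200)

    def test_degenerate_roi_raises(self):
        obj = _object_from_mask(np.ones((500, 600), bool))
        with pytest.raises(R.DegenerateROIError):
            R.extract_roi(obj, EP=(10, 0), UP=(400, 380), BP=(400, 400))


class TestNormalizeROI:
    @pytest.mark.parametrize("shape,expected", [
        ((540, 2000), (270, 1000)),
        ((269, 1000), (269, 1000)),   # identity: already standard width
        ((100, 500), (200, 1000)),
    ])
    def test_sizes(self, shape, expected):
        crop = np.random.default_rng(0).uniform(0, 255, shape)
        out = R.normalize_roi(crop)
        assert out.image.shape == expected

    def test_identity_preserves_values(self):
        crop = np.random.default_rng(1).uniform(0, 255, (269, 1000))
        assert np.allclose(R.normalize_roi(crop).image, crop)


class TestEndToEnd:
    def test_landmark_recovery_within_tolerance(self, cohort_products):
        """EP/UP/BP within 5 px of truth on >= 95% of renders."""
        hits, total = 0, 0
        for rec in cohort_products:
            obj, lm = rec["obj"], rec["roi"].landmarks
            truth = rec["image"].truth["landmarks_canvas"]
            for name, det in (("EP", lm.EP), ("UP", lm.UP), ("BP", lm.BP)):
                gt = obj.to_object(np.array(truth[name]))[0]
                hits += np.hypot(*(np.array(det) - gt)) <= 5.0
                total += 1
        assert hits / total >= 0.95

    def test_roi_repeatability_shift_bound(self, cohort_products):
        """Same fish, different pose: ROI dot sets differ by <= 50 px shift."""
        by_fish = {}
        for rec in cohort_products:
            by_fish.setdefault(rec["fish_id"], []).append(rec["gt_dots_roi"])
        for sets in by_fish.values():
            a, b = sets[0], sets[1]
            delta = b - a
            shift = delta.mean(axis=0)
            assert np.all(np.abs(shift) <= 50.0)
            # residual after removing the shift is small: a pure shift
            assert np.all(np.abs(delta - shift) < 12.0)

    def test_landmarks_inside_object(self, cohort_products):
        for rec in cohort_products[:4]:
            h, w = rec["obj"].mask.shape
            for pt in (rec["roi"].landmarks.EP, rec["roi"].landmarks.UP,
                       rec["roi"].landmarks.BP):
                assert 0 <= pt[0] < w and 0 <= pt[1] < h
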