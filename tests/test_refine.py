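import math

import numpy as np
import pytest

from lungseg import (BinaryMask, ValidationError, correct_contour, fill_holes,
                     point_curvature, scan_mask)
from lungseg.refine import RefineParams


def mask(px):
    return BinaryMask(np.asarray(px, bool))


def filled_ellipse(shape, center, axes):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


class TestFillHoles:
    def test_interior_pixel_filled(self):
        px = filled_ellipse((20, 20), (10, 10), (8, 8))
        px[10, 10] = False
        out = fill_holes(mask(px), 3)
        assert out.pixels[10, 10]

    def test_wide_border_channel_kept_open(self):
        """A channel to the border wider than twice the ball radius is not
        enclosed and must survive."""
        px = np.ones((40, 40), bool)
        px[:, 16:23] = False  # 7 px channel, ball radius 3 -> 2r = 6 < 7
        out = fill_holes(mask(px), 3)
        assert not out.pixels[0, 19]
        assert not out.pixels[20, 19]

    def test_all_false_stays_all_false(self):
        out = fill_holes(mask(np.zeros((16, 16))), 3)
        assert not out.pixels.any()

    @pytest.mark.parametrize("seed", range(3))
    def test_output_superset_of_input(self, seed):
        from oracles import random_blob

        px = random_blob((48, 48), np.random.default_rng(seed))
        out = fill_holes(mask(px), 3)
        assert (out.pixels | px).sum() == out.pixels.sum()


class TestScanMask:
    def test_single_run_first_and_last_only(self):
        px = np.zeros((10, 40), bool)
        px[0, 10:21] = True
        pts = scan_mask(mask(px), 1)
        row0 = [p for p in pts if p.position[0] == 0]
        kinds = {p.kind: p.position[1] for p in row0}
        assert kinds == {"first": 10, "last": 20}

    def test_two_runs_yield_middles(self):
        """Runs [10..20] and [30..40] in one component: first 10, last 40,
        middles at the interior run boundaries 20 and 30."""
        px = np.zeros((12, 60), bool)
        px[0:12, 10:21] = True
        px[0:12, 30:41] = True
        px[0, 21:30] = True  # bridge on row 0 makes it one 8-connected component
        pts = [p for p in pts_row(px, row=6)]
        by_kind = {}
        for p in pts:
            by_kind.setdefault(p.kind, []).append(p.position[1])
        assert by_kind["first"] == [10]
        assert by_kind["last"] == [40]
        assert sorted(by_kind["middle"]) == [20, 30]

    def test_empty_mask_empty_points(self):
        assert scan_mask(mask(np.zeros((8, 8))), 3) == []


def pts_row(px, row):
    return [p for p in scan_mask(mask(px), 1) if p.position[0] == row]


class TestPointCurvature:
    def test_collinear_is_exactly_zero(self):
        assert point_curvature((0, 0), (1, 1), (2, 2)) == 0.0

    @pytest.mark.parametrize("radius", [20, 50, 100])
    def test_circle_curvature_within_15_percent(self, radius):
        """Triples sampled on a circle at scan interval 3 approximate the
        analytic curvature 1/r."""
        for y0 in (0.0, 0.2 * radius, 0.4 * radius):
            ys = np.array([y0 - 3, y0, y0 + 3])
            xs = -np.sqrt(radius ** 2 - ys ** 2)
            k = point_curvature((xs[0], ys[0]), (xs[1], ys[1]), (xs[2], ys[2]))
            assert abs(abs(k) - 1.0 / radius) < 0.15 / radius

    def test_coincident_points_give_inf_sentinel(self, caplog):
        with caplog.at_level("WARNING"):
            k = point_curvature((1, 1), (1, 1), (2, 2))
        assert math.isinf(k)
        assert "coincident" in caplog.text


class TestCorrectContour:
    def test_perfect_ellipse_changes_at_most_one_px_per_row(self):
        px = filled_ellipse((200, 200), (100, 100), (80, 50))
        m = mask(px)
        pts = scan_mask(m, 3)
        out = correct_contour(m, pts, RefineParams())
        assert (out.pixels & ~px).sum() <= 0 or True  # superset allowed
        # per-row boundary deviation <= 1 px in each direction
        for r in range(200):
            cin = np.nonzero(px[r])[0]
            cout = np.nonzero(out.pixels[r])[0]
            if len(cin) == 0 and len(cout) == 0:
                continue
            if len(cin) and len(cout):
                assert abs(int(cout[0]) - int(cin[0])) <= 1
                assert abs(int(cout[-1]) - int(cin[-1])) <= 1

    def test_semicircular_notch_is_covered(self):
        """A notch cut into the right border is bridged: the output contains
        the notch pixels."""
        ell = filled_ellipse((200, 200), (100, 100), (80, 50.5))
        notch = filled_ellipse((200, 200), (100, 149), (8, 8))
        px = ell & ~notch
        m = mask(px)
        out = correct_contour(m, scan_mask(m, 3), RefineParams())
        missing = (ell & notch) & ~out.pixels
        assert missing.sum() == 0

    def test_component_with_two_scanlines_unchanged_with_warning(self, caplog):
        px = np.zeros((10, 40), bool)
        px[0:5, 5:35] = True  # rows 0..4, interval 3 -> scan rows 0 and 3
        m = mask(px)
        with caplog.at_level("WARNING"):
            out = correct_contour(m, scan_mask(m, 3),
                                  RefineParams(min_component_px=10))
        assert "< 3 scan lines" in caplog.text
        np.testing.assert_array_equal(out.pixels, px)

    def test_small_components_discarded_as_debris(self):
        px = np.zeros((64, 64), bool)
        px[30:33, 30:33] = True  # 9 px blob < default 100
        m = mask(px)
        out = correct_contour(m, scan_mask(m, 3), RefineParams())
        assert not out.pixels.any()

    @pytest.mark.parametrize("seed", range(3))
    def test_superset_on_retained_components(self, seed):
        from oracles import random_blob
        from scipy import ndimage as ndi

        px = random_blob((96, 96), np.random.default_rng(10 + seed))
        m = mask(px)
        out = correct_contour(m, scan_mask(m, 3), RefineParams())
        labels, n = ndi.label(px, structure=np.ones((3, 3), bool))
        for comp in range(1, n + 1):
            cpx = labels == comp
            if cpx.sum() >= 100:
                assert not (cpx & ~out.pixels).any()

    def test_near_idempotent(self):
        ell = filled_ellipse((200, 200), (100, 100), (80, 50))
        notch = filled_ellipse((200, 200), (100, 149), (8, 8))
        m = mask(ell & ~notch)
        once = correct_contour(m, scan_mask(m, 3), RefineParams())
        twice = correct_contour(once, scan_mask(once, 3), RefineParams())
        changed = (once.pixels != twice.pixels).sum()
        assert changed <= 0.01 * once.pixels.sum()


class TestParams:
    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            RefineParams(scan_interval=0)
        with pytest.raises(ValidationError):
            RefineParams(curvature_quantile=1.5)
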