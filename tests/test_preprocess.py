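"""Standardization, segmentation, bbox/corner/edge geometry, initialization."""

import itertools

import numpy as np
import pytest
from scipy import stats

import quadstitch as q
from quadstitch.preprocess import (
    GeometryError, SegmentationError, detect_corners_and_edges, initial_align,
    min_area_bbox, segment_tissue, standardize, theil_sen,
)
from quadstitch.raster_core import (
    GrayImage, Quadrant, QuadrantSet, RigidTransform, TissueMask,
)


class TestStandardize:
    def test_identity_on_conforming_input(self):
        arr = np.random.default_rng(0).uniform(0, 1, (40, 60))
        out = standardize(arr, target_max_dim=60)
        assert np.allclose(out.pixels, arr)

    def test_double_horizontal_flip_is_identity(self):
        arr = np.random.default_rng(1).uniform(0, 1, (30, 30))
        once = standardize(arr, flip_h=True, target_max_dim=30)
        twice = standardize(once.pixels, flip_h=True, target_max_dim=30)
        assert np.allclose(twice.pixels, arr)

    def test_pure_red_maps_to_red_luminance_weight(self):
        # ITU-R 709 luminance: Y = 0.2125 R + 0.7154 G + 0.0721 B
        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        rgb[:, :, 0] = 255
        out = standardize(rgb, target_max_dim=8)
        assert np.allclose(out.pixels, 0.2125, atol=1e-4)

    def test_downsampling_adjusts_scale(self):
        arr = np.random.default_rng(2).uniform(0, 1, (128, 64))
        out = standardize(arr, target_max_dim=32, scale_um_per_px=2.0)
        assert out.pixels.shape == (32, 16)
        assert out.scale_um_per_px == pytest.approx(8.0)


class TestSegmentTissue:
    @staticmethod
    def _ellipse_image(n=128, ax=40, ay=25):
        yy, xx = np.mgrid[0:n, 0:n]
        inside = ((xx - n / 2) / ax) ** 2 + ((yy - n / 2) / ay) ** 2 <= 1.0
        img = np.where(inside, 0.3, 1.0)
        return GrayImage(img), inside

    def test_recovers_dark_ellipse(self):
        img, truth = self._ellipse_image()
        mask = segment_tissue(img)
        iou = (mask.bits & truth).sum() / (mask.bits | truth).sum()
        assert iou >= 0.98

    def test_constant_image_rejected(self):
        with pytest.raises(SegmentationError):
            segment_tissue(GrayImage(np.full((32, 32), 0.5)))

    def test_small_speck_removed(self):
        img, truth = self._ellipse_image()
        px = img.pixels.copy()
        px[2:5, 2:5] = 0.2  # distant speck
        mask = segment_tissue(GrayImage(px))
        assert not mask.bits[2:5, 2:5].any()


class TestMinAreaBbox:
    @staticmethod
    def _area(corners):
        x, y = corners[:, 0], corners[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

    def test_axis_aligned_rectangle(self):
        mask = np.zeros((50, 70), dtype=bool)
        mask[10:40, 10:60] = True  # 30 x 50
        corners = min_area_bbox(TissueMask(mask))
        assert self._area(corners) == pytest.approx(1500, abs=1.0)

    def test_rotated_rectangle_matches_bruteforce_oracle(self):
        # oracle: brute-force search over candidate rotations of the same
        # pixel set (pixel squares included), minimal axis-aligned bbox area
        from quadstitch.raster_core import apply_transform
        mask = np.zeros((100, 100), dtype=bool)
        mask[35:65, 20:80] = True  # 30 x 60
        quad = Quadrant("ul", GrayImage(np.full((100, 100), 0.5)),
                        TissueMask(mask))
        t = RigidTransform(theta=30.0, center=(50.0, 50.0))
        _, rotated = apply_transform(quad, t, (100, 100))
        corners = min_area_bbox(rotated)

        ys, xs = np.nonzero(rotated.bits)
        offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
        pts = (np.column_stack([xs, ys])[:, None, :] + offs).reshape(-1, 2)
        best = np.inf
        for ang in np.arange(0.0, 90.0, 0.1):
            a = np.deg2rad(ang)
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            r = pts @ R.T
            area = np.ptp(r[:, 0]) * np.ptp(r[:, 1])
            best = min(best, area)
        assert self._area(corners) == pytest.approx(best, rel=0.02)

    def test_disk(self):
        yy, xx = np.mgrid[0:80, 0:80]
        mask = (xx - 40) ** 2 + (yy - 40) ** 2 <= 30 ** 2
        corners = min_area_bbox(TissueMask(mask))
        assert self._area(corners) == pytest.approx(4 * 30 ** 2, rel=0.02)

    def test_too_few_pixels(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 3] = True
        with pytest.raises(GeometryError):
            min_area_bbox(TissueMask(mask))


class TestTheilSen:
    def test_collinear(self):
        slope, intercept = theil_sen([(0, 0), (1, 1), (2, 2)])
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)

    def test_median_of_pairwise_slopes(self):
        pts = [(0, 0), (1, 1), (2, 2), (3, 10)]
        slopes = sorted((y2 - y1) / (x2 - x1)
                        for (x1, y1), (x2, y2)
                        in itertools.combinations(pts, 2))
        expected = np.median(slopes)
        slope, _ = theil_sen(pts)
        assert slope == pytest.approx(expected)

    def test_robust_to_gross_outliers(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 10, 50)
        y = 2 * x + 1 + rng.normal(0, 0.01, 50)
        xo = rng.uniform(0, 10, 10)
        pts = np.column_stack([np.r_[x, xo], np.r_[y, np.full(10, 100.0)]])
        slope, _ = theil_sen(pts)
        assert abs(slope - 2.0) < 0.05

    def test_matches_scipy_slope(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 50, (30, 2))
        slope, _ = theil_sen(pts)
        ref = stats.theilslopes(pts[:, 1], pts[:, 0])
        assert slope == pytest.approx(ref.slope)

    def test_order_and_duplication_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 20, (15, 2))
        s1, i1 = theil_sen(pts)
        s2, i2 = theil_sen(pts[::-1])
        s3, i3 = theil_sen(np.vstack([pts, pts]))
        assert s1 == pytest.approx(s2)
        assert i1 == pytest.approx(i2)
        assert s1 == pytest.approx(s3)

    def test_degenerate_inputs(self):
        with pytest.raises(GeometryError):
            theil_sen([(1, 1), (1, 1)])
        with pytest.raises(GeometryError):
            theil_sen([(2, 0), (2, 5), (2, 9)])  # vertical: axes must be swapped


def _square_quadrant(label):
    mask = np.zeros((60, 60), dtype=bool)
    mask[10:50, 10:50] = True
    return Quadrant(label, GrayImage(np.full((60, 60), 0.4)), TissueMask(mask))


class TestDetectCornersAndEdges:
    def test_square_ul_edges_are_right_and_bottom(self):
        geom = detect_corners_and_edges(_square_quadrant("ul"))
        v = geom.edges["vertical"].pixels
        h = geom.edges["horizontal"].pixels
        assert np.all(np.abs(v[:, 0] - 49.5) < 2)   # right side x ~ 49.5
        assert np.all(np.abs(h[:, 1] - 49.5) < 2)   # bottom side y ~ 49.5

    def test_square_lr_edges_are_left_and_top(self):
        geom = detect_corners_and_edges(_square_quadrant("lr"))
        v = geom.edges["vertical"].pixels
        h = geom.edges["horizontal"].pixels
        assert np.all(np.abs(v[:, 0] - 9.5) < 2)
        assert np.all(np.abs(h[:, 1] - 9.5) < 2)

    def test_edge_count_and_endpoints(self):
        geom = detect_corners_and_edges(_square_quadrant("ul"))
        assert set(geom.edges) == {"horizontal", "vertical"}
        assert len(geom.corner_points) == 3
        for e in geom.edges.values():
            assert not np.allclose(e.c_in, e.c_out)

    def test_synthetic_edges_track_cut_lines(self, clean_cut_fixture):
        # each detected edge should hug the generator's true cut line
        qs, gt = clean_cut_fixture
        for lbl, quad in qs.items():
            geom = detect_corners_and_edges(quad)
            M = (gt.ul_pose.matrix() @ gt.transforms[lbl].matrix())
            for orient, cut in (("vertical", "vertical"),
                                ("horizontal", "horizontal")):
                px = geom.edges[orient].pixels
                hom = np.column_stack([px, np.ones(len(px))])
                phantom_pts = (hom @ M.T)[:, :2]
                cut_pts = gt.cut_lines[cut]
                d = np.min(np.linalg.norm(
                    phantom_pts[:, None, :] - cut_pts[None, :, :], axis=2),
                    axis=1)
                assert np.mean(d) <= 2.0  # kerf = 0


class TestInitialAlign:
    @staticmethod
    def _prep(qs):
        for _, quad in qs.items():
            if quad.edges is None:
                quad.edges = detect_corners_and_edges(quad)
        return qs

    def test_zero_perturbation_straight_cut_recovery(self):
        img, mask = q.generate_phantom(q.PhantomSpec(seed=10, canvas_px=256))
        spec = q.FragmentSpec(seed=10, cut_amplitude_px=0.0, kerf_px=0.0,
                              translation_range_px=0.0, rotation_range_deg=0.0)
        qs, gt = q.fragment_phantom(img, mask, spec)
        ts = initial_align(self._prep(qs))
        for lbl in ("ur", "ll", "lr"):
            t, tg = ts[lbl], gt.transforms[lbl]
            c = np.array(tg.center)
            assert np.linalg.norm(t.apply(c) - tg.apply(c)) <= 2.0
            assert abs(t.theta - tg.theta) <= 1.0

    def test_rotated_fragments_recovered(self):
        img, mask = q.generate_phantom(q.PhantomSpec(seed=11, canvas_px=256))
        spec = q.FragmentSpec(seed=11, cut_amplitude_px=0.0, kerf_px=0.0,
                              translation_range_px=0.0, rotation_range_deg=10.0)
        qs, gt = q.fragment_phantom(img, mask, spec)
        ts = initial_align(self._prep(qs))
        for lbl in ("ur", "ll", "lr"):
            assert abs(ts[lbl].theta - gt.transforms[lbl].theta) <= 2.0

    def test_kerf_leaves_bounded_gap(self):
        img, mask = q.generate_phantom(q.PhantomSpec(seed=12, canvas_px=256))
        kerf = 5.0
        spec = q.FragmentSpec(seed=12, cut_amplitude_px=0.0, kerf_px=kerf,
                              translation_range_px=0.0, rotation_range_deg=0.0)
        qs, gt = q.fragment_phantom(img, mask, spec)
        ts = initial_align(self._prep(qs))
        from quadstitch.preprocess import ADJACENCIES
        for la, lb, orient in ADJACENCIES:
            ma = ts[la].apply(qs[la].edges.edges[orient].midpoint())[0]
            mb = ts[lb].apply(qs[lb].edges.edges[orient].midpoint())[0]
            # facing midpoints join up to the destroyed band plus tolerance
            assert np.linalg.norm(ma - mb) <= kerf + 2.0

    def test_horizontal_edges_mutually_parallel(self, easy_fixture):
        # the anchor quadrant stays at the identity, so leveling holds up to
        # one global rotation: all horizontal edges must end up parallel
        qs, gt = easy_fixture
        ts = initial_align(self._prep(qs))
        slopes = []
        for lbl, quad in qs.items():
            e = quad.edges.edges["horizontal"]
            pts = ts[lbl].apply(e.pixels)
            slope, _ = theil_sen(pts)
            slopes.append(np.arctan(slope))
        spread = np.rad2deg(max(slopes) - min(slopes))
        assert spread <= 2.0
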