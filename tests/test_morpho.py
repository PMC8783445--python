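"""Skeleton morphometry: fixtures with hand-countable answers plus generator recovery."""

import itertools
import math

import numpy as np
import pytest

from microloh import morpho
from microloh.morpho import BinaryMask, SkeletonMetrics
from microloh.synth.imaging import render_microglia_image


def _mask(arr, pixel_size=1.0):
    return BinaryMask(np.asarray(arr, dtype=bool), pixel_size)


class TestPreprocess:
    def test_all_zero_image_gives_empty_mask(self):
        m = morpho.preprocess(np.zeros((32, 32)), pixel_size=1.0, threshold=10)
        assert not m.data.any()

    def test_single_lit_pixel_removed_by_despeckle(self):
        img = np.zeros((32, 32))
        img[16, 16] = 1_000
        m = morpho.preprocess(img, pixel_size=1.0, threshold=10)
        assert not m.data.any()

    def test_bright_rectangle_preserved(self):
        img = np.zeros((32, 32))
        img[10:20, 5:25] = 1_000
        m = morpho.preprocess(img, pixel_size=1.0, threshold=10)
        assert m.data[12:18, 7:23].all()
        assert not m.data[:8].any()

    def test_otsu_fallback_separates_foreground(self):
        img = np.full((32, 32), 10.0)
        img[8:24, 8:24] = 2_000
        m = morpho.preprocess(img, pixel_size=1.0)  # no threshold given
        assert m.data[10:22, 10:22].all() and not m.data[0:4, 0:4].any()


class TestSkeletonize:
    def test_one_pixel_line_unchanged(self):
        arr = np.zeros((10, 30), dtype=bool)
        arr[5, 2:28] = True
        sk = morpho.skeletonize_mask(_mask(arr))
        np.testing.assert_array_equal(sk.data, arr)

    def test_filled_rectangle_thins_to_horizontal_line(self):
        arr = np.zeros((9, 27), dtype=bool)
        arr[3:6, 3:24] = True  # 21 x 3 rectangle
        sk = morpho.skeletonize_mask(_mask(arr))
        # a 1-px line along the long axis (thinning may leave a 1-px elbow)
        assert sk.data.sum() <= 21
        assert sk.data[4, 4:21].all()
        from scipy import ndimage
        assert ndimage.label(sk.data, structure=np.ones((3, 3)))[1] == 1
        m = morpho.analyze_skeleton(sk)
        assert m.n_endpoints == 2 and m.n_junctions == 0

    def test_empty_mask_stays_empty(self):
        sk = morpho.skeletonize_mask(_mask(np.zeros((5, 5))))
        assert not sk.data.any()

    def test_component_count_preserved(self):
        arr = np.zeros((40, 40), dtype=bool)
        arr[5:10, 5:20] = True
        arr[25:30, 22:37] = True
        from scipy import ndimage
        sk = morpho.skeletonize_mask(_mask(arr))
        assert ndimage.label(sk.data, structure=np.ones((3, 3)))[1] == 2


class TestAnalyzeSkeleton:
    def test_plus_sign_endpoints_and_junction(self):
        arr = np.zeros((25, 25), dtype=bool)
        arr[12, 2:23] = True
        arr[2:23, 12] = True
        m = morpho.analyze_skeleton(_mask(arr))
        assert m.n_endpoints == 4
        assert m.n_junctions == 1

    @pytest.mark.parametrize("pixel_size", [1.0, 0.5])
    def test_straight_line_length_is_steps_times_pixel_size(self, pixel_size):
        arr = np.zeros((5, 60), dtype=bool)
        arr[2, 5:55] = True  # 50 pixels -> 49 steps
        m = morpho.analyze_skeleton(_mask(arr, pixel_size))
        assert m.n_endpoints == 2
        assert m.total_length == pytest.approx(49 * pixel_size)

    def test_diagonal_steps_count_sqrt2(self):
        arr = np.zeros((20, 20), dtype=bool)
        for i in range(10):
            arr[i + 3, i + 3] = True
        m = morpho.analyze_skeleton(_mask(arr))
        assert m.total_length == pytest.approx(9 * math.sqrt(2))

    def test_empty_skeleton_all_zero(self):
        m = morpho.analyze_skeleton(_mask(np.zeros((8, 8))))
        assert (m.n_endpoints, m.n_junctions, m.total_length) == (0, 0, 0.0)

    def test_invariant_under_rotation_and_reflection(self):
        rng = np.random.default_rng(4)
        img = render_microglia_image(n_cells=4, n_reporter_negative=0, seed=5)
        sk = morpho.skeletonize_mask(
            morpho.preprocess(img.channel_iba1, 1.0, threshold=100)
        )
        base = morpho.analyze_skeleton(sk)
        for transform in (np.rot90, np.fliplr, np.flipud):
            m = morpho.analyze_skeleton(_mask(transform(sk.data)))
            assert m.n_endpoints == base.n_endpoints
            assert m.n_junctions == base.n_junctions
            assert m.total_length == pytest.approx(base.total_length)


class TestCountCells:
    def test_two_disjoint_disks(self):
        from skimage.draw import disk
        arr = np.zeros((64, 64), dtype=bool)
        for center in ((16, 16), (48, 48)):
            rr, cc = disk(center, 6)
            arr[rr, cc] = True
        assert morpho.count_cells(_mask(arr), min_soma_area=10) == 2

    def test_empty_mask_zero_cells(self):
        assert morpho.count_cells(_mask(np.zeros((16, 16)))) == 0


class TestSubtraction:
    def test_identical_channels_cancel(self):
        m = SkeletonMetrics(10, 3, 120.0, n_cells=5)
        out = morpho.subtract_channel_metrics(m, m)
        assert (out.n_endpoints, out.n_junctions, out.total_length, out.n_cells) == (0, 0, 0.0, 0)

    def test_empty_reporter_is_identity(self):
        m = SkeletonMetrics(10, 3, 120.0, n_cells=5)
        out = morpho.subtract_channel_metrics(m, SkeletonMetrics(0, 0, 0.0, 0))
        assert out == m

    def test_floors_at_zero(self):
        a = SkeletonMetrics(1, 0, 10.0, n_cells=1)
        b = SkeletonMetrics(5, 2, 50.0, n_cells=3)
        out = morpho.subtract_channel_metrics(a, b)
        assert out.n_endpoints == 0 and out.total_length == 0.0


class TestGeneratorRecovery:
    def test_star_cells_recovered_exactly(self):
        """Unbranched cells: endpoint counts and cell counts exact, length within 10%."""
        for seed in range(3):
            img = render_microglia_image(
                n_cells=8, n_reporter_negative=2, branch_prob=0.0, seed=seed
            )
            m = morpho.frame_metrics(img.channel_iba1, img.pixel_size, threshold=100)
            truth_end = sum(c.n_endpoints for c in img.cells)
            truth_len = sum(c.skeleton_length_um for c in img.cells)
            assert m.n_cells == 8
            assert m.n_endpoints == truth_end
            assert m.total_length == pytest.approx(truth_len, rel=0.10)

    def test_reporter_negative_metrics_from_subtraction(self):
        img = render_microglia_image(n_cells=10, n_reporter_negative=2, seed=1)
        m1 = morpho.frame_metrics(img.channel_iba1, img.pixel_size, threshold=100)
        m2 = morpho.frame_metrics(img.channel_reporter, img.pixel_size, threshold=100)
        neg = morpho.subtract_channel_metrics(m1, m2)
        truth_len = sum(c.skeleton_length_um for c in img.cells if not c.reporter_positive)
        assert neg.n_cells == 2
        assert neg.total_length == pytest.approx(truth_len, rel=0.10)
        assert neg.length_per_cell == pytest.approx(truth_len / 2, rel=0.10)

    def test_reporter_negative_zero_makes_channels_identical(self):
        img = render_microglia_image(n_cells=5, n_reporter_negative=0, seed=2)
        np.testing.assert_array_equal(img.channel_iba1, img.channel_reporter)

    def test_generator_preconditions(self):
        with pytest.raises(ValueError):
            render_microglia_image(n_cells=3, n_reporter_negative=4)
        with pytest.raises(RuntimeError):
            render_microglia_image(n_cells=200, shape=(300, 300), max_retries=50)


def _bruteforce_hull_area(pts):
    """Independent oracle: hull vertices by point-in-triangle tests, then shoelace."""
    def in_triangle(p, a, b, c):
        def cross(o, u, v):
            return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])
        d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
        neg = min(d1, d2, d3) < -1e-12
        pos = max(d1, d2, d3) > 1e-12
        return not (neg and pos)

    hull_pts = []
    for i, p in enumerate(pts):
        others = [q for j, q in enumerate(pts) if j != i]
        interior = any(
            in_triangle(p, a, b, c) and
            abs((b[0]-a[0])*(c[1]-a[1]) - (b[1]-a[1])*(c[0]-a[0])) > 1e-12
            for a, b, c in itertools.combinations(others, 3)
        )
        if not interior:
            hull_pts.append(p)
    cx = sum(p[0] for p in hull_pts) / len(hull_pts)
    cy = sum(p[1] for p in hull_pts) / len(hull_pts)
    hull_pts.sort(key=lambda p: math.atan2(p[1] - cy, p[0] - cx))
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull_pts, hull_pts[1:] + hull_pts[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2


class TestConvexHull:
    def test_unit_square(self):
        area, degenerate = morpho.convex_hull_area([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert area == pytest.approx(1.0)
        assert not degenerate

    def test_collinear_points_degenerate(self):
        area, degenerate = morpho.convex_hull_area([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert area == 0.0 and degenerate

    def test_fewer_than_three_points_degenerate(self):
        assert morpho.convex_hull_area([(0, 0), (1, 1)]) == (0.0, True)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n = int(rng.integers(4, 11))
            pts = [tuple(xy) for xy in rng.uniform(0, 100, size=(n, 2))]
            area, degenerate = morpho.convex_hull_area(pts)
            assert not degenerate
            assert area == pytest.approx(_bruteforce_hull_area(pts), rel=1e-9)
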