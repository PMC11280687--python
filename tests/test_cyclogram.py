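import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from cyclogait import cyclogram as cg
from cyclogait import synthetic as sg
from cyclogait.events import GaitCycle

from conftest import random_simple_polygon


def make_cyclogram(points, stance_boundary=None, dt=0.004, plane="sagittal"):
    pts = np.asarray(points, dtype=float)
    if stance_boundary is None:
        stance_boundary = len(pts) * 6 // 10
    return cg.Cyclogram(points=pts, plane=plane, stance_boundary=stance_boundary, dt=dt)


def circle_points(r=10.0, n=256):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]
TRIANGLE_345 = [(0, 0), (4, 0), (0, 3)]


class TestBuildCyclogram:
    def _cycle(self, angles):
        return GaitCycle(angles=angles, stance_boundary=154, subject_id="S0",
                         side="L", cycle_index=0, duration_s=1.0)

    def test_plane_selects_correct_channels(self):
        angles = np.tile(np.arange(6.0), (256, 1))
        c = self._cycle(angles)
        for plane, (h, k) in {"sagittal": (0, 1), "transverse": (2, 3), "coronal": (4, 5)}.items():
            out = cg.build_cyclogram(c, plane)
            assert np.all(out.hip == h) and np.all(out.knee == k)

    def test_unknown_plane_rejected(self):
        c = self._cycle(np.zeros((256, 6)))
        with pytest.raises(sg.ValidationError):
            cg.build_cyclogram(c, "frontal")

    def test_hip_equals_knee_on_diagonal(self):
        angles = np.zeros((256, 6))
        angles[:, 0] = angles[:, 1] = np.linspace(-10, 30, 256)
        out = cg.build_cyclogram(self._cycle(angles), "sagittal")
        np.testing.assert_array_equal(out.hip, out.knee)

    def test_constant_cycle_perimeter_zero(self):
        angles = np.full((256, 6), 7.0)
        out = cg.build_cyclogram(self._cycle(angles), "sagittal")
        assert cg.perimeter(out, "total") == 0.0


class TestPerimeter:
    def test_unit_square(self):
        assert cg.perimeter(make_cyclogram(UNIT_SQUARE, 2), "total") == pytest.approx(4.0)

    def test_345_triangle(self):
        assert cg.perimeter(make_cyclogram(TRIANGLE_345, 1), "total") == pytest.approx(12.0)

    def test_circle_limit(self):
        p = cg.perimeter(make_cyclogram(circle_points()), "total")
        assert abs(p - 20 * np.pi) / (20 * np.pi) < 1e-3

    def test_stance_swing_total_partition(self):
        pts = np.asarray(random_simple_polygon(np.random.default_rng(0), 40))
        c = make_cyclogram(pts, stance_boundary=24)
        closure = float(np.hypot(*(pts[0] - pts[-1])))
        total = cg.perimeter(c, "stance") + cg.perimeter(c, "swing") + closure
        assert cg.perimeter(c, "total") == pytest.approx(total, rel=1e-12)

    def test_rotation_invariance_of_total(self):
        rng = np.random.default_rng(1)
        pts = random_simple_polygon(rng, 30)
        base = cg.perimeter(make_cyclogram(pts), "total")
        for shift in (3, 11, 27):
            rolled = np.roll(pts, shift, axis=0)
            assert cg.perimeter(make_cyclogram(rolled), "total") == pytest.approx(base)

    def test_matches_shapely_on_random_polygons(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pts = random_simple_polygon(rng)
            ours = cg.perimeter(make_cyclogram(pts), "total")
            theirs = Polygon(pts).exterior.length
            assert ours == pytest.approx(theirs, rel=1e-9)


class TestPerimeterFromVelocity:
    def test_unit_square_identity(self):
        pts = np.asarray(UNIT_SQUARE + [UNIT_SQUARE[0]], dtype=float)
        dt = 0.25
        wh = np.diff(pts[:, 0]) / dt
        wk = np.diff(pts[:, 1]) / dt
        assert cg.perimeter_from_velocity(wh, wk, dt) == pytest.approx(4.0)

    def test_identity_on_random_curves(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(8, 200))
            pts = rng.normal(0, 20, (n, 2))
            dt = float(rng.uniform(0.001, 0.1))
            closed = np.vstack([pts, pts[:1]])
            wh = np.diff(closed[:, 0]) / dt
            wk = np.diff(closed[:, 1]) / dt
            a = cg.perimeter(make_cyclogram(pts, n // 2), "total")
            b = cg.perimeter_from_velocity(wh, wk, dt)
            assert abs(a - b) <= 1e-12 * max(1.0, abs(a))

    def test_zero_dt_degenerate(self):
        assert cg.perimeter_from_velocity(np.ones(5), np.ones(5), 0.0) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(sg.ValidationError):
            cg.perimeter_from_velocity(np.ones(5), np.ones(4), 0.1)


class TestArea:
    def test_unit_square(self):
        assert cg.area(make_cyclogram(UNIT_SQUARE, 2), "total") == pytest.approx(1.0)

    def test_345_triangle(self):
        assert cg.area(make_cyclogram(TRIANGLE_345, 1), "total") == pytest.approx(6.0)

    def test_circle_limit(self):
        a = cg.area(make_cyclogram(circle_points()), "total")
        assert abs(a - 100 * np.pi) / (100 * np.pi) < 1e-3

    def test_orientation_invariant_absolute(self):
        pts = np.asarray(UNIT_SQUARE, dtype=float)
        assert cg.area(make_cyclogram(pts[::-1].copy(), 2), "total") == pytest.approx(1.0)

    def test_matches_shapely_on_random_polygons(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            pts = random_simple_polygon(rng)
            ours = cg.area(make_cyclogram(pts), "total")
            theirs = Polygon(pts).area
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        pts = random_simple_polygon(rng, 25)
        base = cg.area(make_cyclogram(pts), "total")
        for shift in (1, 7, 19):
            assert cg.area(make_cyclogram(np.roll(pts, shift, axis=0)), "total") == pytest.approx(base)

    def test_sub_segment_closed_by_chord(self):
        # stance points of the unit square: (0,0),(1,0),(1,1) -> right triangle
        c = make_cyclogram(UNIT_SQUARE, stance_boundary=2)
        assert cg.area(c, "stance") == pytest.approx(0.5)
        # swing from boundary 1: (1,0),(1,1),(0,1) + chord -> right triangle
        c2 = make_cyclogram(UNIT_SQUARE, stance_boundary=1)
        assert cg.area(c2, "swing") == pytest.approx(0.5)

    def test_too_few_points_rejected(self):
        c = make_cyclogram(UNIT_SQUARE, stance_boundary=1)
        with pytest.raises(sg.ValidationError):
            cg.area(c, "swing") if False else cg.area(
                make_cyclogram([(0, 0), (1, 1)], 1), "total"
            )


class TestCentroidAndMeans:
    def test_unit_square(self):
        com_h, com_k, mean_h, mean_k, flag = cg.centroid_and_means(
            make_cyclogram(UNIT_SQUARE, 2)
        )
        assert (com_h, com_k) == pytest.approx((0.5, 0.5))
        assert (mean_h, mean_k) == pytest.approx((0.5, 0.5))
        assert not flag

    def test_l_shape_centroid_differs_from_vertex_mean(self):
        pts = [(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)]
        com_h, com_k, mean_h, mean_k, _ = cg.centroid_and_means(make_cyclogram(pts, 3))
        # decomposition oracle: two rectangles of areas 2 and 1
        assert (com_h, com_k) == pytest.approx((2.5 / 3, 2.5 / 3))
        assert (mean_h, mean_k) == pytest.approx((1.0, 1.0))
        assert (com_h, com_k) != (mean_h, mean_k)

    def test_matches_shapely_centroid(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            pts = random_simple_polygon(rng)
            com_h, com_k, *_ = cg.centroid_and_means(make_cyclogram(pts))
            c = Polygon(pts).centroid
            assert (com_h, com_k) == pytest.approx((c.x, c.y), rel=1e-9, abs=1e-9)

    def test_degenerate_falls_back_to_vertex_mean(self):
        pts = np.full((10, 2), 3.5)
        com_h, com_k, mean_h, mean_k, flag = cg.centroid_and_means(make_cyclogram(pts, 5))
        assert flag
        assert (com_h, com_k) == (mean_h, mean_k) == (3.5, 3.5)


class TestRangeOfMotion:
    def test_hip_sweep(self):
        pts = np.zeros((50, 2))
        pts[:, 0] = np.linspace(-10, 30, 50)
        rom_h, rom_k = cg.range_of_motion(make_cyclogram(pts, 25))
        assert rom_h == pytest.approx(40.0)
        assert rom_k == 0.0

    @given(offset=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance(self, offset):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 15, (30, 2))
        a = cg.range_of_motion(make_cyclogram(pts, 15))
        b = cg.range_of_motion(make_cyclogram(pts + offset, 15))
        assert a == pytest.approx(b, abs=1e-9)


class TestFeatureVectors:
    def _random_cycle(self, seed):
        rng = np.random.default_rng(seed)
        angles = rng.normal(0, 15, (256, 6))
        return GaitCycle(angles=angles, stance_boundary=154, subject_id="S0",
                         side="L", cycle_index=0, duration_s=1.1)

    def test_length_and_order(self):
        vec = cg.cycle_feature_vector(self._random_cycle(0))
        assert vec.shape == (36,)
        assert len(cg.FEATURE_NAMES) == 36
        assert cg.FEATURE_NAMES[0] == "sagittal_rom_hip"
        assert cg.FEATURE_NAMES[-1] == "coronal_area_total"

    def test_two_identical_cycles_average_to_single(self):
        c = self._random_cycle(1)
        single = cg.subject_feature_vector(
            {p: [cg.build_cyclogram(c, p)] for p in sg.PLANES}
        )
        double = cg.subject_feature_vector(
            {p: [cg.build_cyclogram(c, p)] * 2 for p in sg.PLANES}
        )
        np.testing.assert_allclose(single, double, rtol=1e-12)

    def test_shuffle_invariance(self):
        cycles = [self._random_cycle(s) for s in range(4)]
        by_plane = {p: [cg.build_cyclogram(c, p) for c in cycles] for p in sg.PLANES}
        shuffled = {p: list(reversed(v)) for p, v in by_plane.items()}
        np.testing.assert_allclose(
            cg.subject_feature_vector(by_plane),
            cg.subject_feature_vector(shuffled),
            rtol=1e-12,
        )

    def test_matches_bruteforce_recomputation(self):
        cycles = [self._random_cycle(s) for s in range(3)]
        by_plane = {p: [cg.build_cyclogram(c, p) for c in cycles] for p in sg.PLANES}
        vec = cg.subject_feature_vector(by_plane)
        # independent path: per-cycle dicts averaged feature by feature
        i = 0
        for plane in sg.PLANES:
            for feat in cg.PLANE_FEATURES:
                vals = [cg.cyclogram_features(x)[feat] for x in by_plane[plane]]
                assert vec[i] == pytest.approx(np.mean(vals), rel=1e-12), (plane, feat)
                i += 1

    def test_missing_plane_raises_naming_it(self):
        c = self._random_cycle(2)
        by_plane = {p: [cg.build_cyclogram(c, p)] for p in ("sagittal", "coronal")}
        with pytest.raises(sg.ValidationError, match="transverse"):
            cg.subject_feature_vector(by_plane)
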