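import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curvecage.curves import (
    ConstraintPointSet,
    CrossSectionPlane,
    CurveConstraint,
    SharedCurve,
    collect_frame_constraints,
    interpolate_curve,
    load_curves_json,
    realize_shared_curve,
    resample_equal_interval,
    save_curves_json,
)
from curvecage.errors import ConstraintError, CurveError, ParameterError

XY = CrossSectionPlane("XY", 0.0)


def circle_points(n=8, r=10.0, phase=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return r * np.stack([np.cos(th), np.sin(th)], axis=1)


class TestPlane:
    @pytest.mark.parametrize(
        "axis,uv,expect",
        [
            ("XY", (1.0, 2.0), (1.0, 2.0, 7.0)),
            ("YZ", (1.0, 2.0), (7.0, 1.0, 2.0)),
            ("ZX", (1.0, 2.0), (2.0, 7.0, 1.0)),
        ],
    )
    def test_lift_axis_order(self, axis, uv, expect):
        p = CrossSectionPlane(axis, 7.0)
        np.testing.assert_allclose(p.lift(np.array([uv]))[0], expect)

    def test_project_inverts_lift(self):
        p = CrossSectionPlane("ZX", -3.0)
        uv = np.array([[1.5, -2.5], [0.0, 4.0]])
        np.testing.assert_allclose(p.project(p.lift(uv)), uv)

    def test_bad_axis(self):
        with pytest.raises(ParameterError):
            CrossSectionPlane("XZ", 0.0)


class TestCurveConstraintValidation:
    def test_needs_three_points(self):
        with pytest.raises(CurveError):
            CurveConstraint("c", XY, np.array([[0, 0], [1, 0]]))

    def test_duplicate_points_rejected(self):
        with pytest.raises(CurveError):
            CurveConstraint("c", XY, np.array([[0, 0], [1, 0], [1, 0], [0, 1]]))

    def test_closing_duplicate_rejected(self):
        with pytest.raises(CurveError):
            CurveConstraint("c", XY, np.array([[0, 0], [1, 0], [0, 1], [0, 0]]),
                            closed=True)


class TestInterpolateCurve:
    def test_passes_through_control_points(self):
        cp = circle_points(8)
        c = CurveConstraint("c", XY, cp, closed=True)
        poly = interpolate_curve(c, 64)
        cp3 = XY.lift(cp)
        for p in cp3:
            assert np.linalg.norm(poly - p, axis=1).min() < 1e-6

    def test_triangle_threefold_symmetry(self):
        cp = circle_points(3, r=5.0)
        c = CurveConstraint("tri", XY, cp, closed=True)
        poly = interpolate_curve(c, 128)[:, :2]
        ang = 2 * np.pi / 3
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = poly @ R.T
        from scipy.spatial import cKDTree

        d, _ = cKDTree(poly).query(rotated)
        assert d.max() < 1e-9

    def test_collinear_degenerates_to_segment(self):
        cp = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.5, 0.0]])
        c = CurveConstraint("lin", XY, cp, closed=False)
        poly = interpolate_curve(c, 64)
        assert np.abs(poly[:, 1]).max() < 1e-6
        assert poly[:, 0].min() >= -1e-9 and poly[:, 0].max() <= 3.5 + 1e-9

    def test_circle_radial_deviation(self):
        # oracle: the analytic circle; threshold locked from the oracle run
        # (measured 0.031 mm on the radius-10, 8-point fixture)
        c = CurveConstraint("circ", XY, circle_points(8, 10.0), closed=True)
        poly = interpolate_curve(c, 64)
        r = np.linalg.norm(poly[:, :2], axis=1)
        assert np.abs(r - 10.0).max() < 0.2

    def test_open_curve_hits_endpoints(self):
        cp = np.array([[0, 0], [1, 1], [2, 0], [3, -1]], dtype=float)
        c = CurveConstraint("o", XY, cp, closed=False)
        poly = interpolate_curve(c, 32)
        np.testing.assert_allclose(poly[0, :2], cp[0], atol=1e-12)
        np.testing.assert_allclose(poly[-1, :2], cp[-1], atol=1e-12)

    def test_planarity(self):
        p = CrossSectionPlane("YZ", 4.5)
        c = CurveConstraint("c", p, circle_points(6), closed=True)
        poly = interpolate_curve(c, 32)
        assert (poly[:, 0] == 4.5).all()

    def test_catmull_rom_fallback(self):
        cp = circle_points(8, 10.0)
        c = CurveConstraint("c", XY, cp, closed=True)
        poly = interpolate_curve(c, 64, model="catmull-rom")
        r = np.linalg.norm(poly[:, :2], axis=1)
        assert np.abs(r - 10.0).max() < 0.2

    def test_unknown_model(self):
        c = CurveConstraint("c", XY, circle_points(4), closed=True)
        with pytest.raises(ParameterError):
            interpolate_curve(c, 16, model="bezier9000")


class TestResample:
    def test_straight_segment(self):
        ps = resample_equal_interval(
            np.array([[0, 0, 0], [10, 0, 0]]), 2.0, closed=False
        )
        np.testing.assert_allclose(ps.points[:, 0], [0, 2, 4, 6, 8, 10])

    def test_closed_square(self):
        sq = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], dtype=float)
        ps = resample_equal_interval(sq, 5.0, closed=True)
        assert len(ps) == 8
        gaps = np.linalg.norm(
            np.diff(np.vstack([ps.points, ps.points[:1]]), axis=0), axis=1
        )
        np.testing.assert_allclose(gaps, 5.0, atol=1e-12)

    def test_circle_count_and_uniformity(self):
        c = CurveConstraint("c", XY, circle_points(8, 10.0), closed=True)
        poly = interpolate_curve(c, 64)
        ps = resample_equal_interval(poly, 1.0, closed=True)
        assert len(ps) in (62, 63)
        gaps = np.linalg.norm(np.diff(ps.points, axis=0), axis=1)
        assert (gaps.max() - gaps.min()) / gaps.mean() < 0.01

    def test_interval_longer_than_polyline(self):
        ps = resample_equal_interval(
            np.array([[0, 0, 0], [1, 0, 0]]), 5.0, closed=False
        )
        assert len(ps) == 2

    def test_bad_interval(self):
        with pytest.raises(ParameterError):
            resample_equal_interval(np.zeros((4, 3)), -1.0)

    @settings(max_examples=25, deadline=None)
    @given(
        n=st.integers(5, 24),
        r=st.floats(3.0, 40.0),
        d=st.floats(0.3, 2.0),
    )
    def test_spacing_uniform_property(self, n, r, d):
        c = CurveConstraint("c", XY, circle_points(n, r), closed=True)
        poly = interpolate_curve(c, 48)
        ps = resample_equal_interval(poly, d, closed=True)
        if len(ps) < 3:
            return
        gaps = np.linalg.norm(np.diff(ps.points, axis=0), axis=1)
        assert (gaps.max() - gaps.min()) / gaps.mean() < 0.01


class TestSharedCurve:
    def make(self):
        return SharedCurve(
            "s",
            XY,
            keyframes={
                0: np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                10: np.array([[10.0, 0.0], [11.0, 0.0], [10.0, 1.0]]),
            },
        )

    def test_linear_midpoint(self):
        c = realize_shared_curve(self.make(), 5, 20)
        np.testing.assert_allclose(c.control_points[0], [5.0, 0.0], atol=1e-12)

    def test_keyframe_verbatim(self):
        s = self.make()
        c = realize_shared_curve(s, 10, 20)
        np.testing.assert_array_equal(c.control_points, s.keyframes[10])

    def test_hold_before_and_after(self):
        s = self.make()
        np.testing.assert_array_equal(
            realize_shared_curve(s, 15, 20).control_points, s.keyframes[10]
        )

    def test_single_keyframe_constant(self):
        s = SharedCurve("s", XY, {3: circle_points(4)})
        for t in range(6):
            np.testing.assert_array_equal(
                realize_shared_curve(s, t, 6).control_points, s.keyframes[3]
            )

    def test_count_mismatch_rejected(self):
        with pytest.raises(CurveError):
            SharedCurve("s", XY, {0: circle_points(4), 1: circle_points(5)})

    def test_out_of_range_frame(self):
        with pytest.raises(ParameterError):
            realize_shared_curve(self.make(), 25, 20)

    @settings(max_examples=25, deadline=None)
    @given(t=st.integers(0, 10))
    def test_piecewise_linearity_in_t(self, t):
        s = self.make()
        c = realize_shared_curve(s, t, 11)
        w = t / 10.0
        expect = (1 - w) * s.keyframes[0] + w * s.keyframes[10]
        np.testing.assert_allclose(c.control_points, expect, atol=1e-12)


class TestCollect:
    def test_concatenation_counts(self):
        local = CurveConstraint("a", XY, circle_points(8, 10.0), frame=2)
        shared = SharedCurve("s", CrossSectionPlane("YZ", 0.0),
                             {0: circle_points(8, 5.0)})
        ps = collect_frame_constraints([local], [shared], 2, 5, interval=1.0)
        a = collect_frame_constraints([local], [], 2, 5, interval=1.0)
        b = collect_frame_constraints([], [shared], 2, 5, interval=1.0)
        assert len(ps) == len(a) + len(b)
        assert set(ps.sources) == {"a", "s@2"}

    def test_shared_only_frame_nonempty(self):
        shared = SharedCurve("s", XY, {0: circle_points(8, 5.0)})
        for t in range(4):
            ps = collect_frame_constraints([], [shared], t, 4)
            assert len(ps) > 0

    def test_empty_inputs_error(self):
        with pytest.raises(ConstraintError):
            collect_frame_constraints([], [], 0, 5)

    def test_local_curve_only_on_its_frame(self):
        local = CurveConstraint("a", XY, circle_points(8, 10.0), frame=1)
        with pytest.raises(ConstraintError):
            collect_frame_constraints([local], [], 0, 3)

    def test_planarity_of_collected_points(self):
        p = CrossSectionPlane("ZX", 2.5)
        local = CurveConstraint("a", p, circle_points(8, 10.0), frame=0)
        ps = collect_frame_constraints([local], [], 0, 1)
        assert (ps.points[:, 1] == 2.5).all()


class TestJson:
    def test_roundtrip(self, tmp_path):
        path = str(tmp_path / "curves.json")
        curves = [
            CurveConstraint("a", XY, circle_points(5), closed=True, frame=0),
            CurveConstraint("b", CrossSectionPlane("YZ", 3.0),
                            circle_points(4), closed=False, frame=2),
        ]
        shared = [SharedCurve("s", CrossSectionPlane("ZX", -1.0),
                              {0: circle_points(6), 4: circle_points(6, 12.0)})]
        save_curves_json(path, 5, curves, shared)
        frames, c2, s2 = load_curves_json(path)
        assert frames == 5
        assert [c.id for c in c2] == ["a", "b"]
        assert c2[1].frame == 2 and not c2[1].closed
        np.testing.assert_allclose(c2[0].control_points, curves[0].control_points)
        assert s2[0].plane == shared[0].plane
        np.testing.assert_allclose(s2[0].keyframes[4], shared[0].keyframes[4])

    def test_schema_shape(self, tmp_path):
        path = str(tmp_path / "curves.json")
        save_curves_json(path, 2, [CurveConstraint("a", XY, circle_points(3), frame=0)])
        doc = json.loads(open(path).read())
        assert set(doc) == {"frames", "curves", "shared_curves"}
        c = doc["curves"][0]
        assert c["plane"] == {"axis": "XY", "offset_mm": 0.0}
        assert isinstance(c["control_points_mm"][0], list)
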