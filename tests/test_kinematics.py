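"""Geometry of the per-frame features: line fit, areas, head elevation, neck angle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitkit as gk
from gaitkit.kinematics import GeometryError, back_points_array, frame_features

from conftest import make_pose


def brute_force_rmse(pts: np.ndarray) -> float:
    """Independent OLS residual oracle via the normal equations."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    res = y - A @ coef
    return float(np.sqrt((res**2).mean()))


def shoelace(pts: np.ndarray) -> float:
    """Absolute area of the closed polygon through the 5 points."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


arched_toplines = st.builds(
    lambda xs, hs: np.column_stack([np.sort(np.array([0.0, *xs, 100.0])),
                                    [0.0, *hs, 0.0]]),
    st.lists(st.floats(1.0, 99.0), min_size=3, max_size=3, unique=True),
    st.lists(st.floats(0.0, 50.0), min_size=3, max_size=3),
)


class TestBackFit:
    def test_collinear_points_have_zero_rmse(self):
        pts = np.array([(x, 2 * x + 1) for x in range(5)], float)
        fit = gk.fit_back_line(pts)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_zigzag_worked_example(self):
        fit = gk.fit_back_line(np.array([(0, 0), (1, 1), (2, 0), (3, 1), (4, 0)], float))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.4)
        assert fit.residuals == pytest.approx((-0.4, 0.6, -0.4, 0.6, -0.4))
        assert fit.rmse == pytest.approx(0.4899, abs=1e-4)

    def test_taller_arch_raises_rmse(self):
        low = gk.fit_back_line(np.array([(0, 0), (1, 1), (2, 0), (3, 1), (4, 0)], float))
        arch = gk.fit_back_line(
            np.array([(0, 0), (1, 1.5), (2, 2), (3, 1.5), (4, 0)], float))
        assert arch.rmse == pytest.approx(0.8367, abs=1e-4)
        assert arch.rmse > low.rmse

    def test_vertical_topline_rejected(self):
        pts = np.array([(2.0, y) for y in range(5)], float)
        with pytest.raises(GeometryError, match="vertical"):
            gk.fit_back_line(pts)

    def test_rmse_invariant_to_translation(self, rng):
        pts = rng.normal(size=(5, 2)) * 20
        pts[:, 0] = np.sort(pts[:, 0]) + np.arange(5)  # distinct x
        a = gk.fit_back_line(pts).rmse
        b = gk.fit_back_line(pts + [123.0, -45.0]).rmse
        assert b == pytest.approx(a, abs=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=5))
    def test_rmse_matches_brute_force_oracle(self, heights):
        pts = np.column_stack([np.arange(5.0) * 7.0, heights])
        assert gk.fit_back_line(pts).rmse == pytest.approx(
            brute_force_rmse(pts), abs=1e-12)


class TestBackAreas:
    def test_tent_worked_example(self):
        areas = gk.back_areas(np.array([(0, 0), (1, 1), (2, 2), (3, 1), (4, 0)], float))
        assert areas.total == pytest.approx(4.0)
        assert areas.back_hip_to_centre == pytest.approx(2.0)
        assert areas.front_shoulder_to_centre == pytest.approx(1.5)
        assert areas.neck_to_shoulder == pytest.approx(0.5)

    def test_collinear_topline_has_zero_area(self):
        pts = np.array([(x, 3.0 + 0.5 * x) for x in range(5)], float)
        areas = gk.back_areas(pts)
        assert areas.total == pytest.approx(0.0, abs=1e-12)

    def test_sections_sum_to_total(self, rng):
        for _ in range(50):
            pts = np.column_stack([np.sort(rng.uniform(0, 100, 5)),
                                   rng.uniform(-20, 20, 5)])
            if pts[0, 0] == pts[4, 0]:
                continue
            a = gk.back_areas(pts)
            assert a.total == pytest.approx(
                a.back_hip_to_centre + a.front_shoulder_to_centre + a.neck_to_shoulder,
                rel=1e-9, abs=1e-9)

    def test_rigid_motion_invariance(self):
        pts = np.array([(0, 0), (1, 1), (2, 2), (3, 1), (4, 0)], float)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [57.0, -12.0]
        a, b = gk.back_areas(pts), gk.back_areas(moved)
        assert b.total == pytest.approx(a.total, abs=1e-9)
        assert b.back_hip_to_centre == pytest.approx(a.back_hip_to_centre, abs=1e-9)
        assert b.front_shoulder_to_centre == pytest.approx(
            a.front_shoulder_to_centre, abs=1e-9)
        assert b.neck_to_shoulder == pytest.approx(a.neck_to_shoulder, abs=1e-9)

    def test_image_convention_arch_is_positive(self):
        # image coords: arching lowers y; area must still be positive
        pts = np.array([(0, 300), (100, 295), (200, 290), (300, 295), (400, 300)],
                       float)
        assert gk.back_areas(pts).total > 0

    def test_sway_back_segment_is_negative(self):
        pts = np.array([(0, 0), (1, 2), (2, 2), (3, -1), (4, 0)], float)
        a = gk.back_areas(pts)
        assert a.neck_to_shoulder < 0
        assert a.total == pytest.approx(
            a.back_hip_to_centre + a.front_shoulder_to_centre + a.neck_to_shoulder)

    def test_zero_length_baseline_rejected(self):
        pts = np.array([(0, 0), (1, 1), (2, 2), (3, 1), (0, 0)], float)
        with pytest.raises(GeometryError, match="baseline"):
            gk.back_areas(pts)

    @given(arched_toplines)
    def test_total_matches_shoelace_oracle_on_arched_toplines(self, pts):
        total = gk.back_areas(pts).total
        assert total == pytest.approx(shoelace(pts), rel=1e-9, abs=1e-9)

    def test_scaling_arch_height_scales_area_and_rmse(self):
        base = np.array([(0, 0), (1, 1), (2, 2), (3, 1), (4, 0)], float)
        k = 2.5
        tall = base.copy()
        tall[:, 1] *= k
        assert gk.back_areas(tall).total == pytest.approx(
            k * gk.back_areas(base).total)
        assert gk.fit_back_line(tall).rmse > gk.fit_back_line(base).rmse


class TestHeadElevation:
    @pytest.fixture
    def flat_fit(self):
        return gk.fit_back_line(np.array([(x, 10.0) for x in range(5)], float))

    def test_point_above_line_is_positive(self, flat_fit):
        he = gk.head_nose_pos(flat_fit, head=(6.0, 7.0), nose=(7.0, 7.0))
        assert he.head_pos == pytest.approx(9.0)

    def test_point_below_line_is_negative(self, flat_fit):
        he = gk.head_nose_pos(flat_fit, head=(6.0, 13.0), nose=(7.0, 13.0))
        assert he.head_pos == pytest.approx(-9.0)

    def test_point_on_line_is_zero(self, flat_fit):
        he = gk.head_nose_pos(flat_fit, head=(6.0, 10.0), nose=(7.0, 10.0))
        # fit of a flat topline carries float-epsilon slope; squared offsets
        # are zero to far below any physical scale
        assert he.head_pos == pytest.approx(0.0, abs=1e-20)
        assert he.nose_pos == pytest.approx(0.0, abs=1e-20)
        assert he.combined == pytest.approx(0.0, abs=1e-20)

    def test_antisymmetry_under_reflection_about_line(self, flat_fit):
        up = gk.head_nose_pos(flat_fit, head=(6.0, 10.0 - 3.3), nose=(7.0, 10.0 - 1.1))
        down = gk.head_nose_pos(flat_fit, head=(6.0, 10.0 + 3.3), nose=(7.0, 10.0 + 1.1))
        assert up.head_pos == pytest.approx(-down.head_pos)
        assert up.nose_pos == pytest.approx(-down.nose_pos)
        assert up.combined == pytest.approx(-down.combined)

    def test_combined_is_mean_of_head_and_nose(self, flat_fit):
        he = gk.head_nose_pos(flat_fit, head=(6.0, 8.0), nose=(7.0, 11.0))
        assert he.combined == pytest.approx((he.head_pos + he.nose_pos) / 2)

    def test_sloped_line_evaluated_at_point_x(self):
        fit = gk.fit_back_line(np.array([(x, 2.0 * x) for x in range(5)], float))
        he = gk.head_nose_pos(fit, head=(10.0, 15.0), nose=(10.0, 25.0))
        assert he.head_pos == pytest.approx(25.0)   # line y=20, head 5 above
        assert he.nose_pos == pytest.approx(-25.0)  # 5 below


class TestNeckAngle:
    def test_unit_slope_gives_45_degrees(self):
        # m1 = 1 (withers->scapula), m2 = 0 (scapula->head)
        ng = gk.neck_angle(withers=(0, 0), scapula=(1, 1), head=(2, 1))
        assert ng.m1 == pytest.approx(1.0) and ng.m2 == pytest.approx(0.0)
        assert ng.angle == pytest.approx(math.pi / 4, abs=1e-4)

    def test_antisymmetric_case_gives_minus_45(self):
        ng = gk.neck_angle(withers=(0, 0), scapula=(1, 0), head=(2, 1))
        assert ng.angle == pytest.approx(-math.pi / 4, abs=1e-4)

    def test_equal_gradients_give_zero(self):
        ng = gk.neck_angle(withers=(0, 0), scapula=(1, 0.5), head=(2, 1.0))
        assert ng.angle == 0.0

    def test_perpendicular_gradients_give_half_pi(self):
        # m1 = 2, m2 = -1/2 -> 1 + m1*m2 = 0
        ng = gk.neck_angle(withers=(0, 0), scapula=(1, 2), head=(3, 1))
        assert ng.angle == pytest.approx(math.pi / 2)
        ng2 = gk.neck_angle(withers=(0, 0), scapula=(1, -2), head=(3, -1))
        assert ng2.angle == pytest.approx(-math.pi / 2)

    def test_angle_in_half_open_interval(self, rng):
        for _ in range(200):
            w, s, h = rng.uniform(-10, 10, size=(3, 2))
            if w[0] == s[0] or s[0] == h[0]:
                continue
            ng = gk.neck_angle(tuple(w), tuple(s), tuple(h))
            assert -math.pi / 2 < ng.angle <= math.pi / 2

    def test_vertical_segment_names_culprit(self):
        with pytest.raises(GeometryError, match="withers"):
            gk.neck_angle((1, 0), (1, 5), (2, 5))
        with pytest.raises(GeometryError, match="head"):
            gk.neck_angle((0, 0), (1, 5), (1, 6))


class TestFrameFeatures:
    def test_partial_visibility_sets_only_back_features(self, full_pose):
        pose = full_pose
        del pose.points["head"]
        pose.visibility["head"] = gk.Visibility.ABSENT
        ff = frame_features(pose)
        assert ff.back_rmse is not None and ff.area_total is not None
        assert ff.head_nose_pos is None and ff.neck_angle is None

    def test_zero_arch_zero_noise_is_flat(self):
        params = gk.GaitParams(keypoint_noise_sd=0.0,
                               flex_amplitude_by_score=(0.0, 0.0, 0.0, 0.0))
        track = gk.simulate_cow_track(params, 0, seed=1, n_frames=3)
        for pose in track.poses:
            ff = frame_features(pose)
            assert ff.back_rmse == pytest.approx(0.0, abs=1e-9)
            assert ff.area_total == pytest.approx(0.0, abs=1e-9)

    def test_composition_equals_component_ops(self, full_pose):
        ff = frame_features(full_pose)
        pts = back_points_array(full_pose)
        fit = gk.fit_back_line(pts)
        areas = gk.back_areas(pts)
        assert ff.back_rmse == fit.rmse
        assert ff.area_total == areas.total
        assert ff.head_nose_pos == gk.head_nose_pos(
            fit, full_pose.xy("head"), full_pose.xy("nose")).combined
        assert ff.neck_angle == gk.neck_angle(
            full_pose.xy("withers"), full_pose.xy("scapula"),
            full_pose.xy("head")).angle

    def test_features_translation_invariant_where_expected(self, full_pose):
        shifted_points = {n: (x + 500.0, y - 80.0)
                          for n, (x, y) in full_pose.points.items()}
        shifted = make_pose(shifted_points)
        a, b = frame_features(full_pose), frame_features(shifted)
        assert b.back_rmse == pytest.approx(a.back_rmse, abs=1e-9)
        assert b.area_total == pytest.approx(a.area_total, abs=1e-9)
        assert b.head_nose_pos == pytest.approx(a.head_nose_pos, abs=1e-6)
        assert b.neck_angle == pytest.approx(a.neck_angle, abs=1e-12)
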