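"""Egocentric feature geometry: closed forms, invariances, oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socivis.geometry import (
    Pose, TrajectorySet, angle_subtended_tangents, angular_height,
    angular_position, angular_velocity, angular_width,
    cross_section_half_length, compute_features, flies_within_body_lengths,
    nearest_conspecific, summarize_features, to_egocentric,
)

from _oracles import chord_half_length_numeric, ellipse_boundary_extent

finite = st.floats(-50, 50, allow_nan=False)
angle = st.floats(0, 2 * math.pi, allow_nan=False)


class TestFrameTransform:
    def test_identity(self):
        sub = Pose(0, 0, 0, 1.0, 0.5)
        assert to_egocentric(sub, (1, 0)) == pytest.approx((1, 0))

    def test_rotation(self):
        sub = Pose(0, 0, math.pi / 2, 1.0, 0.5)
        # target 1 mm ahead of a north-facing subject is straight ahead
        assert to_egocentric(sub, (0, 1)) == pytest.approx((1, 0), abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(sx=finite, sy=finite, sh=angle, tx=finite, ty=finite,
           gx=finite, gy=finite, gh=angle)
    def test_rigid_motion_leaves_egocentric_coords_unchanged(
            self, sx, sy, sh, tx, ty, gx, gy, gh):
        sub = Pose(sx, sy, sh, 1.2, 0.5)
        e0 = to_egocentric(sub, (tx, ty))
        c, s = math.cos(gh), math.sin(gh)

        def move(x, y):
            return (gx + c * x - s * y, gy + s * x + c * y)

        sub2 = Pose(*move(sx, sy), sh + gh, 1.2, 0.5)
        e1 = to_egocentric(sub2, move(tx, ty))
        assert e1 == pytest.approx(e0, abs=1e-8)


class TestAngularPosition:
    @pytest.mark.parametrize("xy,expected", [
        ((1, 1), 45.0), ((-1, 0), 180.0), ((0, -1), -90.0), ((1, 0), 0.0)])
    def test_full_quadrant(self, xy, expected):
        assert angular_position(*xy) == pytest.approx(expected)

    def test_origin_is_flagged_nan(self):
        assert math.isnan(angular_position(0.0, 0.0))

    @settings(deadline=None, max_examples=50)
    @given(x=finite, y=finite)
    def test_matches_atan2_oracle(self, x, y):
        if x == 0 and y == 0:
            return
        got = angular_position(x, y)
        assert math.radians(got) == pytest.approx(
            math.atan2(y, x) if math.atan2(y, x) != -math.pi else math.pi, abs=1e-12)


class TestAngularVelocity:
    def test_linear_ramp_at_170fps(self):
        theta = np.arange(100, dtype=float)  # 1 degree per frame
        phi = angular_velocity(theta, fps=170.0)
        assert np.allclose(phi, 170.0)

    def test_wraparound_produces_no_spike(self):
        theta = np.mod(np.arange(0, 720, 2.0) + 180, 360.0) - 180.0
        phi = angular_velocity(theta, fps=10.0)
        assert np.allclose(phi, 20.0)

    def test_sinusoid_matches_analytic_derivative(self):
        fps = 170.0
        t = np.arange(0, 2, 1 / fps)
        theta = 40 * np.sin(2 * np.pi * t)
        phi = angular_velocity(theta, fps)
        expected = 40 * 2 * np.pi * np.cos(2 * np.pi * t)
        # central differences: O(dt^2) interior, one-sided at endpoints
        assert np.abs(phi[1:-1] - expected[1:-1]).max() < 0.2
        assert np.abs(phi - expected).max() < 6.0

    def test_nan_frames_propagate(self):
        theta = np.array([0.0, 1.0, np.nan, 3.0, 4.0, 5.0])
        phi = angular_velocity(theta, fps=1.0)
        assert np.isnan(phi[1:4]).all()
        assert np.isfinite(phi[[0, 4, 5]]).all()

    def test_integral_recovers_net_angle_change(self):
        rng = np.random.default_rng(0)
        fps = 100.0
        theta = np.cumsum(rng.normal(0, 2, 400))
        wrapped = np.mod(theta + 180, 360) - 180
        phi = angular_velocity(wrapped, fps)
        # trapezoid of central differences telescopes to the net change
        net = np.trapezoid(phi, dx=1 / fps)
        assert net == pytest.approx(theta[-1] - theta[0], abs=1e-6)


class TestCrossSection:
    def test_circle_any_sight_line(self):
        tgt = Pose(5, 5, 0.7, 1.0, 1.0)
        for ang in np.linspace(0, 2 * np.pi, 7):
            R = cross_section_half_length(tgt, (5 + 3 * np.cos(ang),
                                                5 + 3 * np.sin(ang)))
            assert R == pytest.approx(1.0)

    def test_sight_along_major_axis_gives_minor(self):
        tgt = Pose(0, 0, 0, 2.0, 0.5)
        assert cross_section_half_length(tgt, (-4, 0)) == pytest.approx(0.5)

    def test_sight_along_minor_axis_gives_major(self):
        tgt = Pose(0, 0, 0, 2.0, 0.5)
        assert cross_section_half_length(tgt, (0, -4)) == pytest.approx(2.0)

    @settings(deadline=None, max_examples=40)
    @given(h=angle, sight=angle, a=st.floats(0.5, 3), ratio=st.floats(0.2, 1))
    def test_matches_numeric_chord_oracle(self, h, sight, a, ratio):
        b = a * ratio
        tgt = Pose(0, 0, h, a, b)
        nose = (10 * math.cos(sight), 10 * math.sin(sight))
        R = cross_section_half_length(tgt, nose)
        # chord direction perpendicular to the sight line
        d = (math.sin(sight), -math.cos(sight))
        expected = chord_half_length_numeric(0, 0, h, a, b, d)
        assert R == pytest.approx(expected, rel=1e-9)
        assert b - 1e-9 <= R <= a + 1e-9


class TestAngularSize:
    def test_width_equals_90_when_R_equals_d(self):
        assert angular_width(0.7, 0.7) == pytest.approx(90.0)

    def test_width_inverse_formula(self):
        d = 0.5 / math.tan(math.radians(15))
        assert angular_width(0.5, d) == pytest.approx(30.0)

    def test_width_decreases_monotonically_to_zero(self):
        ds = np.linspace(0.5, 100, 200)
        ws = [angular_width(1.0, d) for d in ds]
        assert all(a > b for a, b in zip(ws, ws[1:]))
        assert ws[-1] < 2.0

    @pytest.mark.parametrize("d,expected", [(0.8660254, 60.0), (0.5, 90.0)])
    def test_height_formula(self, d, expected):
        assert angular_height(d) == pytest.approx(expected, abs=1e-4)

    def test_height_below_width_when_R_exceeds_half_height(self):
        for d in (0.5, 1, 3, 10):
            assert angular_height(d) < angular_width(0.8, d)


class TestOccludedAngle:
    def test_circle_closed_form_at_distance_two(self):
        # tangents to a unit circle from 2 radii away: 2*arcsin(1/2) = 60 deg
        tgt = Pose(0, 0, 0, 1.0, 1.0)
        assert angle_subtended_tangents((2, 0), tgt) == pytest.approx(60.0, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(d=st.floats(1.05, 200), ang=angle, r=st.floats(0.2, 2))
    def test_circle_matches_arcsin_closed_form(self, d, ang, r):
        tgt = Pose(3, -2, 0.3, r, r)
        nose = (3 + r * d * math.cos(ang), -2 + r * d * math.sin(ang))
        expected = math.degrees(2 * math.asin(1 / d))
        assert angle_subtended_tangents(nose, tgt) == pytest.approx(
            expected, abs=1e-6)

    def test_vanishes_at_large_distance(self):
        tgt = Pose(0, 0, 0, 1.0, 1.0)
        assert angle_subtended_tangents((1e5, 0), tgt) < 0.01

    def test_nose_inside_ellipse_flagged(self):
        tgt = Pose(0, 0, 0, 2.0, 1.0)
        assert math.isnan(angle_subtended_tangents((0.5, 0), tgt))
        assert angle_subtended_tangents((0.5, 0), tgt, inside="full") == 360.0

    @pytest.mark.parametrize("seed", range(6))
    def test_ellipse_matches_boundary_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.5, 2.5)
        b = a * rng.uniform(0.2, 1.0)
        h = rng.uniform(0, 2 * np.pi)
        cx, cy = rng.uniform(-5, 5, 2)
        tgt = Pose(cx, cy, h, a, b)
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(1.2 * a, 6 * a)
        nose = (cx + dist * np.cos(ang), cy + dist * np.sin(ang))
        got = angle_subtended_tangents(nose, tgt)
        expected = ellipse_boundary_extent(nose, cx, cy, h, a, b, n=40000)
        assert got == pytest.approx(expected, abs=0.02)

    def test_decreases_with_distance(self):
        tgt = Pose(0, 0, 0.9, 1.5, 0.6)
        vals = [angle_subtended_tangents((d, 0.3), tgt) for d in (2, 3, 5, 9, 20)]
        assert all(x > y for x, y in zip(vals, vals[1:]))


def _traj(rows, fps=170.0):
    return TrajectorySet(
        data=pd.DataFrame(rows, columns=["frame", "fly_id", "x_mm", "y_mm",
                                         "heading_rad", "a_mm", "b_mm"]),
        fps=fps)


class TestArenaQueries:
    def test_nearest_picks_closer_fly(self):
        t = _traj([(0, 0, 0, 0, 0, 1, .5), (0, 1, 2, 0, 0, 1, .5),
                   (0, 2, 4, 0, 0, 1, .5)])
        tid, d = nearest_conspecific(t, 0, 0)
        assert tid == 1 and d == pytest.approx(1.0)  # nose at (1, 0)

    def test_equal_distances_break_to_lower_id(self):
        t = _traj([(0, 0, 0, 0, 0, 1, .5), (0, 5, 3, 0, 0, 1, .5),
                   (0, 2, -1, 0, 0, 1, .5)])
        # nose at (1,0): fly 5 at 2 mm, fly 2 at 2 mm -> lower id wins
        tid, d = nearest_conspecific(t, 0, 0)
        assert tid == 2 and d == pytest.approx(2.0)

    def test_nan_positions_are_skipped(self):
        t = _traj([(0, 0, 0, 0, 0, 1, .5), (0, 1, np.nan, 0, 0, 1, .5),
                   (0, 2, 5, 0, 0, 1, .5)])
        assert nearest_conspecific(t, 0, 0)[0] == 2

    def test_body_length_count(self):
        # subject body length 2 mm -> k=2 radius 4 mm
        t = _traj([(0, 0, 0, 0, 0, 1, .5), (0, 1, 3.8, 0, 0, 1, .5),
                   (0, 2, 4.2, 0, 0, 1, .5)])
        assert flies_within_body_lengths(t, 0, 0, k=2) == 1
        assert flies_within_body_lengths(t, 0, 0, k=0) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_queries_match_pairwise_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        rows = [(0, i, *rng.uniform(-20, 20, 2), rng.uniform(0, 2 * np.pi),
                 1.3, 0.6) for i in range(n)]
        t = _traj(rows)
        for subject in range(n):
            sub = t.pose(subject, 0)
            nose = sub.nose
            dists = {i: math.hypot(r[2] - nose[0], r[3] - nose[1])
                     for i, r in zip(range(n), rows) if i != subject}
            best = min(sorted(dists), key=lambda i: dists[i])
            assert nearest_conspecific(t, subject, 0) == (
                best, pytest.approx(dists[best]))
            cdists = {i: math.hypot(r[2] - sub.x, r[3] - sub.y)
                      for i, r in zip(range(n), rows) if i != subject}
            expected = sum(d <= 2 * sub.body_length for d in cdists.values())
            assert flies_within_body_lengths(t, subject, 0, k=2) == expected


class TestSummaries:
    def test_constant_feature_summary(self):
        feats = pd.DataFrame({"w_deg": [30.0] * 5, "h_deg": [20.0] * 5,
                              "theta_deg": [0.0] * 5, "d_mm": [4.0] * 5})
        out = summarize_features(feats, np.ones(5, bool))
        assert out.loc["w_deg", "mean"] == 30.0
        assert out.loc["w_deg", "sd"] == 0.0
        assert out.loc["w_deg", "n_frames"] == 5

    def test_two_frame_mean(self):
        feats = pd.DataFrame({"w_deg": [20.0, 40.0], "h_deg": [1, 1],
                              "theta_deg": [0, 0], "d_mm": [1, 1]})
        out = summarize_features(feats, np.ones(2, bool))
        assert out.loc["w_deg", "mean"] == 30.0

    def test_empty_mask_is_an_error(self):
        feats = pd.DataFrame({"w_deg": [1.0], "h_deg": [1.0],
                              "theta_deg": [0.0], "d_mm": [1.0]})
        with pytest.raises(ValueError, match="empty"):
            summarize_features(feats, np.zeros(1, bool))


class TestFeatureTableInvariance:
    def test_features_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(2)
        rows, rows2 = [], []
        gx, gy, gh = 7.0, -3.0, 1.1
        c, s = math.cos(gh), math.sin(gh)
        for f in range(5):
            for fly in range(3):
                x, y = rng.uniform(-10, 10, 2)
                h = rng.uniform(0, 2 * math.pi)
                rows.append((f, fly, x, y, h, 1.3, 0.6))
                rows2.append((f, fly, gx + c * x - s * y, gy + s * x + c * y,
                              h + gh, 1.3, 0.6))
        f1 = compute_features(_traj(rows), 0)
        f2 = compute_features(_traj(rows2), 0)
        pd.testing.assert_frame_equal(f1, f2, check_exact=False, atol=1e-8)
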