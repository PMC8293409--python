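"""Viewing-geometry closed forms checked against numeric ray constructions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vergesize.geometry import (
    ViewingGeometry,
    angular_size_of_offset_disc,
    distance_from_vergence,
    mean_target_speed,
    mean_vergence_rate,
    project_constant_angle_target,
    screen_target_separation,
    vergence_angle,
    vergence_range_fraction,
)


def vergence_angle_raytrace(d: float, ipd: float) -> float:
    """Independent oracle: angle between the two lines of sight, built from
    the eye positions and the fixation point as explicit vectors."""
    left, right = np.array([-ipd / 2, 0.0]), np.array([ipd / 2, 0.0])
    fix = np.array([0.0, d])
    u, v = fix - left, fix - right
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


def separation_raytrace(D: float, d: float, ipd: float) -> float:
    """Oracle: intersect each eye's crossed line of sight with the display
    plane z = D and measure the lateral gap between the two hits."""
    # left eye at -i/2 looks through (0, d); parametrise and evaluate at z=D
    x_right_target = -ipd / 2 + (ipd / 2) / d * D
    x_left_target = ipd / 2 - (ipd / 2) / d * D
    return float(x_right_target - x_left_target)


class TestVergenceAngle:
    def test_matches_ray_intersection_oracle(self):
        for d in [10.0, 25.0, 50.0, 160.0, 1000.0]:
            for ipd in [5.5, 6.0, 6.3, 7.2]:
                assert vergence_angle(d, ipd) == pytest.approx(
                    vergence_angle_raytrace(d, ipd), abs=1e-9
                )

    def test_printed_viewing_distances(self):
        assert vergence_angle(25, 6.3) == pytest.approx(14.36, abs=5e-3)
        assert vergence_angle(50, 6.3) == pytest.approx(7.21, abs=5e-3)

    def test_infinite_distance_limit(self):
        assert vergence_angle(np.inf, 6.3) == 0.0
        assert vergence_angle(1e9, 6.3) == pytest.approx(0.0, abs=1e-6)

    @given(st.floats(1.0, 500.0), st.floats(5.0, 8.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_roundtrip(self, d, ipd):
        assert distance_from_vergence(vergence_angle(d, ipd), ipd) == pytest.approx(
            d, rel=1e-8
        )

    def test_strictly_decreasing_and_convex(self):
        d = np.linspace(5, 300, 200)
        v = vergence_angle(d, 6.3)
        assert np.all(np.diff(v) < 0)
        assert np.all(np.diff(v, 2) > 0)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            vergence_angle(bad, 6.3)
        with pytest.raises(ValueError):
            vergence_angle(25.0, bad)


class TestTrialKinematics:
    def test_printed_mean_vergence_rate(self):
        g = ViewingGeometry()  # 50 -> 25 cm over 5 s, IPD 6.3
        assert round(mean_vergence_rate(g), 1) == 1.4
        assert mean_vergence_rate(g) == pytest.approx(1.4306, abs=1e-3)

    def test_mean_target_speed(self):
        assert mean_target_speed(ViewingGeometry()) == pytest.approx(5.0)

    def test_static_fixation_zero_rate(self):
        g = ViewingGeometry(fixation_start=50, fixation_end=50, duration=3.0)
        assert mean_vergence_rate(g) == 0.0

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            ViewingGeometry(duration=0.0)


class TestScreenTargetSeparation:
    def test_matches_ray_oracle_on_grid(self):
        for D in [100.0, 160.0, 200.0]:
            for d in [20.0, 25.0, 50.0, 99.0]:
                for ipd in [5.8, 6.0, 6.3]:
                    assert screen_target_separation(D, d, ipd) == pytest.approx(
                        separation_raytrace(D, d, ipd), abs=1e-9
                    )

    def test_printed_separations(self):
        assert screen_target_separation(160, 50, 6.0) == pytest.approx(13.2)
        assert screen_target_separation(160, 25, 6.0) == pytest.approx(32.4)

    def test_fixation_at_screen(self):
        assert screen_target_separation(160, 160, 6.0) == 0.0

    def test_monotone_decreasing_in_fixation_distance(self):
        d = np.linspace(20, 160, 50)
        seps = [screen_target_separation(160, di, 6.3) for di in d]
        assert np.all(np.diff(seps) < 0)

    def test_uncrossed_rejected(self):
        with pytest.raises(ValueError):
            screen_target_separation(160, 170, 6.3)


class TestConstantAngleProjection:
    def test_normal_gaze_extent(self):
        e0, e1 = project_constant_angle_target(0.0, 160.0, 160.0, 3.0)
        assert e1 - e0 == pytest.approx(2 * 160 * np.tan(np.radians(1.5)), abs=1e-9)
        assert e1 - e0 == pytest.approx(8.38, abs=5e-3)

    def test_extent_vanishes_with_angle(self):
        e0, e1 = project_constant_angle_target(0.0, 160.0, 160.0, 1e-6)
        assert e1 - e0 == pytest.approx(0.0, abs=1e-5)

    def test_oblique_gaze_asymmetry(self):
        # right eye (+3 cm) converging on the midline at 25 cm: gaze points
        # leftward, so the ray at gaze - half_extent is the more oblique one
        # and its half-extent on the screen must be the larger
        lo_edge, hi_edge = project_constant_angle_target(3.0, 25.0, 160.0, 3.0)
        gaze_hit = 3.0 + 160.0 * np.tan(np.arctan2(-3.0, 25.0))
        assert abs(gaze_hit - lo_edge) > abs(gaze_hit - hi_edge)

    def test_small_angle_consistency(self):
        for alpha in [0.1, 0.5, 1.0]:
            e0, e1 = project_constant_angle_target(0.0, 160.0, 160.0, alpha)
            ratio = (e1 - e0) / (160.0 * np.radians(alpha))
            assert 1.0 <= ratio <= 1.0002

    def test_ray_parallel_to_screen_rejected(self):
        with pytest.raises(ValueError):
            project_constant_angle_target(0.0, 0.1, 160.0, 3.0, fixation_offset=1e4)


class TestOffsetDiscAngularSize:
    def test_aligned_coin(self):
        assert angular_size_of_offset_disc(0.0, 2.0, 30.0) == pytest.approx(
            3.8183, abs=5e-4
        )

    def test_offset_coin_smaller_than_aligned(self):
        # cross-fused coin: image displaced by one IPD is the smaller one
        off = angular_size_of_offset_disc(6.0, 2.0, 30.0)
        assert off == pytest.approx(3.6717, abs=5e-4)
        assert off < angular_size_of_offset_disc(0.0, 2.0, 30.0)

    @given(st.floats(-10, 10), st.floats(0.5, 4.0), st.floats(10, 100))
    @settings(max_examples=50, deadline=None)
    def test_even_in_offset(self, c, diam, dist):
        assert angular_size_of_offset_disc(c, diam, dist) == pytest.approx(
            angular_size_of_offset_disc(-c, diam, dist), rel=1e-12
        )

    def test_strictly_decreasing_in_abs_offset(self):
        sizes = [angular_size_of_offset_disc(c, 2.0, 30.0) for c in np.linspace(0, 15, 40)]
        assert np.all(np.diff(sizes) < 0)

    def test_far_distance_limit(self):
        assert angular_size_of_offset_disc(0.0, 2.0, 1e9) == pytest.approx(0.0, abs=1e-6)


class TestVergenceRangeFraction:
    def test_near_half_for_25_to_50(self):
        assert vergence_range_fraction(25, 50, 6.3) == pytest.approx(0.50, abs=0.01)

    def test_definition_limits(self):
        assert vergence_range_fraction(25, np.inf, 6.3) == pytest.approx(1.0)
        assert vergence_range_fraction(25, 25.0001, 6.3) == pytest.approx(0.0, abs=1e-4)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            vergence_range_fraction(50, 25, 6.3)
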