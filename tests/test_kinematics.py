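"""Angle-system unit tests: gravity elevation, trunk compensation,
plane of elevation, scapular rotation and the ScAla score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scapkin import kinematics as kin
from scapkin.frame import LEFT, UP
from scapkin.synthetic_cohort import ParticipantSpec, forward_markers

from conftest import random_pose


def make_pose_series(poses, p=None):
    """Marker series whose frame 0 is an upright reference posture."""
    p = p or ParticipantSpec(id="P1", marker_noise_sd=0.0)
    ref = {"theta_gh": 6.0, "rho": 0.0, "kappa": 0.0, "alpha": 80.0}
    rows = [ref] + list(poses)
    return p, forward_markers(
        np.array([r["theta_gh"] for r in rows]),
        np.array([r["rho"] for r in rows]),
        np.array([r["kappa"] for r in rows]),
        np.array([r["alpha"] for r in rows]),
        p,
    )


class TestElevationAngle:
    def test_hanging_arm_is_zero(self):
        assert kin.elevation_angle_gravity(np.zeros(3), [0, 0, -500.0]) == pytest.approx(0.0)

    def test_horizontal_arm_is_ninety(self):
        assert kin.elevation_angle_gravity(np.zeros(3), [500.0, 0, 0]) == pytest.approx(90.0)

    @pytest.mark.parametrize("angle", [5.0, 37.5, 90.0, 143.2, 175.0])
    def test_rotation_oracle(self, angle):
        """Rotating the rest pose by a known angle about a horizontal axis
        must reproduce that angle exactly."""
        rest = np.array([0.0, 0.0, -500.0])
        a = np.deg2rad(angle)
        rot = np.array(
            [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
        )
        assert kin.elevation_angle_gravity(np.zeros(3), rot @ rest) == pytest.approx(angle)

    def test_zero_length_wrist_vector_raises(self):
        with pytest.raises(ValueError, match="zero-length"):
            kin.elevation_angle_gravity(np.zeros(3), np.zeros(3))


class TestPlaneOfElevation:
    def test_forward_reach_alpha_ninety(self):
        u, flagged = kin.plane_of_elevation(np.zeros((1, 3)), np.array([[400.0, 0, 0]]))
        assert not flagged[0]
        assert kin.alpha_plane(LEFT, u)[0] == pytest.approx(90.0)

    def test_sideward_reach_alpha_zero(self):
        u, _ = kin.plane_of_elevation(np.zeros((1, 3)), np.array([[0.0, -400.0, 0]]))
        assert kin.alpha_plane(LEFT, u)[0] == pytest.approx(0.0)

    def test_vertical_wrist_vector_flagged(self):
        _, flagged = kin.plane_of_elevation(np.zeros((1, 3)), np.array([[0.0, 0, -400.0]]))
        assert flagged[0]


class TestTrunkCompensation:
    def test_unchanged_axis_is_zero(self):
        u = np.array([[1.0, 0, 0]])
        assert kin.trunk_compensation(UP[None, :], UP, u)[0] == pytest.approx(0.0)

    def test_inplane_backward_lean(self):
        u = np.array([[1.0, 0, 0]])
        lean = np.deg2rad(10.0)
        s_now = np.array([[-np.sin(lean), 0.0, np.cos(lean)]])
        assert kin.trunk_compensation(s_now, UP, u)[0] == pytest.approx(10.0)

    def test_out_of_plane_lean_takes_inplane_component(self):
        """An oblique lean must match an explicit 3D projection oracle:
        project both axes onto span(u, UP) and take the signed angle."""
        rng = np.random.default_rng(11)
        u = np.array([1.0, 0.0, 0.0])
        for _ in range(20):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(-0.4, 0.4)
            c, s = np.cos(ang), np.sin(ang)
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            rot = np.eye(3) + s * K + (1 - c) * (K @ K)
            s_now = rot @ UP
            # oracle: explicit projection onto the elevation plane
            pn = np.array([u, UP]).T  # plane basis
            v2 = pn.T @ s_now
            v1 = pn.T @ UP
            expect = np.degrees(np.arctan2(v2[1], v2[0]) - np.arctan2(v1[1], v1[0]))
            got = kin.trunk_compensation(s_now[None, :], UP, u[None, :])[0]
            assert got == pytest.approx(expect, abs=1e-9)


class TestArithmeticIdentities:
    def test_theta_identity(self):
        tg = np.array([120.0, 50.0])
        kp = np.array([20.0, 5.0])
        np.testing.assert_allclose(kin.corrected_elevation(tg, kp), [100.0, 45.0])

    def test_gh_identity(self):
        np.testing.assert_allclose(
            kin.glenohumeral_elevation(np.array([90.0]), np.array([30.0])), [60.0]
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            kin.corrected_elevation(np.zeros(3), np.zeros(2))
        with pytest.raises(ValueError, match="mismatch"):
            kin.glenohumeral_elevation(np.zeros(3), np.zeros(4))


class TestScalaScore:
    def test_physiological_rhythm(self):
        tgh = np.linspace(5, 80, 50)
        assert kin.scala_score(tgh, 0.5 * tgh) == pytest.approx(0.5)

    def test_rigid_scapula(self):
        tgh = np.linspace(0, 90, 40)
        assert kin.scala_score(tgh, np.zeros_like(tgh)) == pytest.approx(0.0)

    def test_medial_winging_with_noise(self):
        """Repeated noisy fits of a -0.4 coupling stay within 0.05."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            tgh = np.linspace(5, 90, 120)
            rho = -0.4 * tgh + rng.normal(0, 1.0, size=tgh.size)
            assert kin.scala_score(tgh, rho) == pytest.approx(-0.4, abs=0.05)

    def test_insufficient_range_raises(self):
        tgh = np.linspace(50, 60, 30)
        with pytest.raises(ValueError, match="insufficient elevation range"):
            kin.scala_score(tgh, 0.5 * tgh)

    def test_format(self):
        assert kin.format_scala(0.5) == "1:0.5"
        assert kin.format_scala(-0.42) == "1:-0.4"


class TestSegmentReconstruction:
    def test_upright_thorax_gives_vertical_sternum_axis(self, clean_trial):
        seg = kin.reconstruct_segments(clean_trial.markers)
        np.testing.assert_allclose(seg.sternum_axis[0], UP, atol=1e-12)

    def test_coincident_markers_raise(self, clean_trial):
        m = clean_trial.markers
        for name in m.marker_names:
            m.markers[name] = np.zeros_like(m.markers[name])
        with pytest.raises(ValueError, match="degenerate"):
            kin.reconstruct_segments(m)

    def test_missing_marker_raises(self, clean_trial):
        del clean_trial.markers.markers["C7"]
        with pytest.raises(ValueError, match="required marker"):
            kin.reconstruct_segments(clean_trial.markers)


class TestRoundTrip:
    def test_random_pose_sweep(self):
        """Noise-free forward markers invert to the posed angles <0.1 deg."""
        rng = np.random.default_rng(42)
        poses = [random_pose(rng) for _ in range(30)]
        _, series = make_pose_series(poses)
        ang = kin.compute_angles(series)
        for i, pose in enumerate(poses, start=1):
            tg = pose["theta_gh"] + pose["rho"]
            assert ang.theta_g[i] == pytest.approx(tg, abs=0.1)
            assert ang.kappa[i] == pytest.approx(pose["kappa"], abs=0.1)
            assert ang.theta[i] == pytest.approx(tg - pose["kappa"], abs=0.1)
            assert ang.alpha[i] == pytest.approx(pose["alpha"], abs=0.1)
            assert ang.rho[i] == pytest.approx(pose["rho"], abs=0.1)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        shift=st.tuples(*[st.floats(-500, 500) for _ in range(3)]),
        yaw=st.floats(0, 360),
    )
    def test_translation_and_yaw_invariance(self, shift, yaw):
        """Angles are invariant to global translation and to rotation
        about the gravity axis applied jointly to all markers."""
        rng = np.random.default_rng(9)
        poses = [random_pose(rng) for _ in range(3)]
        _, series = make_pose_series(poses)
        ref = kin.compute_angles(series)
        a = np.deg2rad(yaw)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        for name in series.marker_names:
            series.markers[name] = series.markers[name] @ rot.T + np.asarray(shift)
        moved = kin.compute_angles(series)
        np.testing.assert_allclose(moved.theta_g, ref.theta_g, atol=1e-8)
        np.testing.assert_allclose(moved.kappa, ref.kappa, atol=1e-8)
        np.testing.assert_allclose(moved.alpha, ref.alpha, atol=1e-8)
        np.testing.assert_allclose(moved.rho, ref.rho, atol=1e-8)

    def test_identities_hold_in_output(self, clean_trial):
        ang = kin.compute_angles(clean_trial.markers)
        ok = ~ang.flags
        np.testing.assert_allclose(
            ang.theta[ok], ang.theta_g[ok] - ang.kappa[ok], atol=1e-12
        )
        np.testing.assert_allclose(
            ang.theta_gh[ok], ang.theta_g[ok] - ang.rho[ok], atol=1e-12
        )
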