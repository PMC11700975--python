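"""Spatial feature equations: angles, rates, ROM, step length."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitmono import (JointTriplet, SignalSeries, finite_rate, knee_angle,
                      rom, spatial_features, step_length_series, thigh_angle)
from gaitmono.errors import DegenerateGeometryError, InsufficientDataError
from gaitmono.pose_model import PoseSequence


def _atan2_angle(u, v):
    """Independent oracle: angle via atan2 of |u x v| and u . v."""
    cross = np.linalg.norm(np.cross(u, v))
    return float(np.arctan2(cross, np.dot(u, v)))


class TestKneeAngle:
    def test_straight_leg_is_pi(self):
        t = JointTriplet(H=np.array([0.0, 0, 0]), K=np.array([0.0, -1, 0]),
                         A=np.array([0.0, -2, 0]))
        assert knee_angle(t) == pytest.approx(np.pi)

    def test_right_angle(self):
        t = JointTriplet(H=np.array([0.0, 0, 0]), K=np.array([0.0, -1, 0]),
                         A=np.array([1.0, -1, 0]))
        assert knee_angle(t) == pytest.approx(np.pi / 2)

    def test_random_triplets_match_atan2_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            H, K, A = rng.normal(0, 100, (3, 3))
            expect = _atan2_angle(H - K, A - K)
            got = knee_angle(JointTriplet(H=H, K=K, A=A))
            assert got == pytest.approx(expect, abs=1e-9)

    def test_degenerate_vector_raises(self):
        t = JointTriplet(H=np.zeros(3), K=np.zeros(3), A=np.ones(3))
        with pytest.raises(DegenerateGeometryError):
            knee_angle(t)


class TestThighAngle:
    def test_parallel_thighs_zero(self):
        v = np.array([0.3, -1.0, 0.1])
        assert thigh_angle(np.zeros(3), v, np.ones(3), np.ones(3) + v) == \
            pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_is_pi(self):
        assert thigh_angle(np.zeros(3), np.array([0, -1.0, 0]),
                           np.zeros(3), np.array([0, 1.0, 0])) == \
            pytest.approx(np.pi)

    def test_random_vs_atan2(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            HL, KL, HR, KR = rng.normal(0, 50, (4, 3))
            assert thigh_angle(HL, KL, HR, KR) == pytest.approx(
                _atan2_angle(KL - HL, KR - HR), abs=1e-9)


class TestFiniteRate:
    def test_constant_series_zero_rate(self):
        s = SignalSeries(np.full(10, 3.3), fs=30.0)
        assert np.allclose(finite_rate(s).values, 0.0)

    def test_linear_ramp_gives_constant_rate(self):
        s = SignalSeries(0.1 * np.arange(20), fs=30.0)
        out = finite_rate(s)
        assert len(out) == 19
        assert np.allclose(out.values, 3.0)

    def test_sine_derivative_bound(self):
        fs = 30.0
        i = np.arange(61)
        s = SignalSeries(np.sin(2 * np.pi * i / 30.0), fs=fs)
        out = finite_rate(s)
        mid_t = (i[1:] - 0.5) / fs
        analytic = 2 * np.pi * np.cos(2 * np.pi * mid_t)
        # backward differences evaluated at midpoints: O(1/fs^2) accurate
        assert np.max(np.abs(out.values - analytic)) < (2 * np.pi) ** 3 / fs ** 2

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            finite_rate(SignalSeries(np.array([1.0]), fs=30.0))


class TestRomAndStepLength:
    def test_rom_examples(self):
        assert rom(SignalSeries(np.full(5, 2.0), fs=30)) == 0.0
        assert rom(SignalSeries(np.array([0.1, 0.9, 0.4]), fs=30)) == \
            pytest.approx(0.8)

    def test_rom_offset_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        assert rom(SignalSeries(x, 30)) == pytest.approx(
            rom(SignalSeries(x + 11.7, 30)))

    def test_step_length_3_4_5(self):
        coords = np.zeros((2, 6, 3))
        coords[:, 4, :] = [0.0, 0, 0]        # ankle_L
        coords[:, 5, :] = [300.0, 400, 0]    # ankle_R
        seq = PoseSequence(coords=coords)
        assert np.allclose(step_length_series(seq).values, 500.0)

    def test_coincident_ankles_zero(self):
        seq = PoseSequence(coords=np.ones((2, 6, 3)))
        assert np.allclose(step_length_series(seq).values, 0.0)

    def test_step_length_symmetric_under_ankle_swap(self, noiseless):
        seq, _ = noiseless
        swapped = seq.coords.copy()
        jm = seq.joint_map
        swapped[:, [jm["ankle_L"], jm["ankle_R"]]] = \
            swapped[:, [jm["ankle_R"], jm["ankle_L"]]]
        other = PoseSequence(coords=swapped, fs=seq.fs, joint_map=jm)
        assert np.allclose(step_length_series(seq).values,
                           step_length_series(other).values)


class TestSpatialFeatures:
    def test_noiseless_knee_rom_matches_preset(self, noiseless):
        seq, truth = noiseless
        feats = spatial_features(seq)
        assert feats["lknee_angle_rom"] == pytest.approx(
            truth.params.knee_rom, rel=0.02)
        assert feats["step_length_max"] == pytest.approx(
            truth.params.step_length, rel=0.02)

    def test_mirror_swap_exchanges_sides(self, noiseless):
        seq, _ = noiseless
        jm = seq.joint_map
        swapped = seq.coords.copy()
        for joint in ("hip", "knee", "ankle"):
            l, r = jm[f"{joint}_L"], jm[f"{joint}_R"]
            swapped[:, [l, r]] = swapped[:, [r, l]]
        other = PoseSequence(coords=swapped, fs=seq.fs, joint_map=jm)
        a = spatial_features(seq)
        b = spatial_features(other)
        for name in ("angle_rom", "angle_velocity_rom", "angle_acc_rom"):
            assert a[f"lknee_{name}"] == pytest.approx(b[f"rknee_{name}"])
            assert a[f"rknee_{name}"] == pytest.approx(b[f"lknee_{name}"])
        assert a["thigh_angle_max"] == pytest.approx(b["thigh_angle_max"])

    def test_static_pose_all_rom_zero(self):
        rng = np.random.default_rng(3)
        frame = rng.normal(0, 200, (1, 6, 3))
        coords = np.repeat(frame, 30, axis=0)
        seq = PoseSequence(coords=coords, fs=30.0)
        feats = spatial_features(seq)
        for name, value in feats.items():
            if name.endswith("_rom"):
                assert value == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, noiseless):
        seq, _ = noiseless
        rng = np.random.default_rng(11)
        R = Rotation.random(random_state=rng).as_matrix()
        shift = rng.normal(0, 500, 3)
        moved = PoseSequence(coords=seq.coords @ R.T + shift, fs=seq.fs,
                             joint_map=seq.joint_map)
        a, b = spatial_features(seq), spatial_features(moved)
        for name in a:
            if "angle" in name:  # angles are rigid-motion invariants
                assert a[name] == pytest.approx(b[name], abs=1e-9)
        assert a["step_length_max"] == pytest.approx(b["step_length_max"],
                                                     abs=1e-6)

    def test_rate_rom_scales_with_fs(self, noiseless):
        seq, _ = noiseless
        from dataclasses import replace
        double = replace(seq, fs=2 * seq.fs)
        a, b = spatial_features(seq), spatial_features(double)
        assert b["lknee_angle_velocity_rom"] == pytest.approx(
            2 * a["lknee_angle_velocity_rom"])
        assert b["thigh_angle_acc_rom"] == pytest.approx(
            4 * a["thigh_angle_acc_rom"])
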