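import numpy as np
import pytest

from fmca import (AngleTrajectory, PatientProfile, extract_features,
                  lowpass_filter, rom, segment_phases, simulate_trial,
                  summary_stat, three_point_angle)
from fmca.features import axial_rotation_angle


class TestThreePointAngle:
    @pytest.mark.parametrize("a, b, c, expected", [
        ((0, 0, 0), (1, 0, 0), (2, 0, 0), 180.0),
        ((0, 1, 0), (0, 0, 0), (1, 0, 0), 90.0),
        ((1, 1, 0), (0, 0, 0), (1, 0, 0), 45.0),
    ])
    def test_closed_forms(self, a, b, c, expected):
        assert three_point_angle(a, b, c) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            three_point_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


def _rodrigues(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    th = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


class TestAxialRotationAngle:
    def test_reference_aligned_is_zero(self):
        # distal already in the rotation plane, coincident with the reference
        ang = axial_rotation_angle(((0, 0, 0), (0, 0, 1)),
                                   ((0, 0, 1), (1, 0, 1)),
                                   reference=(1, 0, 0))
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn(self):
        ang = axial_rotation_angle(((0, 0, 0), (0, 0, 1)),
                                   ((0, 0, 1), (0, 1, 1)),
                                   reference=(1, 0, 0))
        assert abs(ang) == pytest.approx(90.0, abs=1e-9)

    def test_matches_rodrigues_construction(self, rng):
        """Rotating the distal vector by phi about the axis must read phi."""
        for _ in range(50):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ref = rng.normal(size=3)
            r_perp = ref - np.dot(ref, axis) * axis
            if np.linalg.norm(r_perp) < 1e-3:
                continue
            phi = rng.uniform(-179, 179)
            d0 = rng.normal(size=3)
            start = _rodrigues(axis, 0) @ (r_perp / np.linalg.norm(r_perp))
            distal = _rodrigues(axis, phi) @ start
            ang = axial_rotation_angle((d0, d0 + axis), (d0, d0 + distal), ref)
            assert ang == pytest.approx(phi, abs=1e-6)

    def test_degenerate_projection_is_nan(self):
        ang = axial_rotation_angle(((0, 0, 0), (0, 0, 1)),
                                   ((0, 0, 1), (0, 0, 2)),
                                   reference=(1, 0, 0))
        assert np.isnan(ang)


def ramp_traj(t_start=2.0, duration=6.0, rate=30.0, lo=10.0, hi=70.0):
    t = np.arange(int(duration * rate) + 1) / rate
    v = np.where(t < t_start, lo,
                 lo + (hi - lo) * np.minimum((t - t_start) / 2.0, 1.0))
    return AngleTrajectory("ramp", t, v)


class TestSegmentPhases:
    def test_ramp_onset_ends_near_ramp_start(self):
        ph = segment_phases(ramp_traj())
        assert ph.onset[0] == 0.0
        assert 2.0 <= ph.onset[1] <= 2.25
        assert ph.motion[0] == ph.onset[1]
        assert ph.motion[1] >= 4.0  # peak reached at the plateau

    def test_step_function_onset(self):
        t = np.arange(91) / 30.0
        v = np.where(t < 1.0, 0.0, 40.0)
        ph = segment_phases(AngleTrajectory("step", t, v))
        assert ph.onset == (0.0, pytest.approx(1.0, abs=0.05))

    def test_constant_trajectory_warns_full_motion(self):
        t = np.arange(61) / 30.0
        traj = AngleTrajectory("flat", t, np.full_like(t, 33.0))
        with pytest.warns(UserWarning, match="flat"):
            ph = segment_phases(traj)
        assert ph.motion[1] >= t[-1]

    def test_too_short_rejected(self):
        t = np.arange(10) / 30.0
        with pytest.raises(ValueError, match="1 s"):
            segment_phases(AngleTrajectory("short", t, t))


class TestReductions:
    def test_rom_of_sinusoid(self):
        t = np.linspace(0, 10, 2000)
        traj = AngleTrajectory("sin", t, 30 * np.sin(2 * np.pi * 0.5 * t))
        assert rom(traj, (0, 10)) == pytest.approx(60.0, abs=0.01)

    def test_rom_constant_and_ramp(self):
        t = np.linspace(0, 5, 100)
        assert rom(AngleTrajectory("c", t, np.full_like(t, 7.0)), (0, 5)) == 0.0
        assert rom(AngleTrajectory("r", t, np.linspace(10, 70, 100)),
                   (0, 6)) == pytest.approx(60.0)

    def test_mean_and_sd_closed_forms(self):
        t = np.array([0.0, 1.0, 2.0])
        traj = AngleTrajectory("v", t, np.array([10.0, 20.0, 30.0]))
        assert summary_stat(traj, (0, 3), "mean") == pytest.approx(20.0)
        assert summary_stat(traj, (0, 3), "sd") == pytest.approx(10.0)

    def test_sd_of_uniform_noise_matches_analytic(self, rng):
        t = np.linspace(0, 100, 20000)
        width = 12.0
        traj = AngleTrajectory("u", t, rng.uniform(0, width, size=t.size))
        analytic = width / np.sqrt(12.0)
        assert summary_stat(traj, (0, 101), "sd") == pytest.approx(
            analytic, rel=0.05)

    def test_sd_single_sample_rejected(self):
        t = np.array([0.0, 1.0])
        traj = AngleTrajectory("v", t, np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="2 samples"):
            summary_stat(traj, (0, 0.5), "sd")

    def test_time_reindexing_invariance(self):
        t = np.linspace(0, 5, 200)
        v = np.sin(t) * 20
        a = AngleTrajectory("a", t, v)
        b = AngleTrajectory("b", 2.0 * t + 3.0, v)
        assert rom(a, (0, 6)) == rom(b, (0, 14))
        assert summary_stat(a, (0, 6), "mean") == summary_stat(b, (0, 14), "mean")


def _rigidly_transform(seq, R, shift):
    out = seq.positions @ R.T + shift
    from fmca import SkeletonSequence
    return SkeletonSequence(t=seq.t, landmarks=list(seq.landmarks),
                            positions=out, sample_rate=seq.sample_rate,
                            side=seq.side, meta=dict(seq.meta))


class TestExtractFeatures:
    @pytest.mark.parametrize("test_id, expected", [
        ("T1", {"F_Va": 60.0}),
        ("T3", {"F_Vb_1": 40.0, "F_Vb_2": 30.0}),
    ])
    def test_recovers_commanded_rom(self, clean_trials, test_id, expected):
        fv = extract_features(lowpass_filter(clean_trials[test_id]), test_id)
        for k, v in expected.items():
            assert fv[k] == pytest.approx(v, abs=1.0)

    def test_partial_ability_rom(self):
        seq = simulate_trial(PatientProfile(ability=0.4, seed=9), "T3")
        fv = extract_features(lowpass_filter(seq), "T3")
        assert fv["F_Vb_1"] == pytest.approx(16.0, abs=1.0)
        assert fv["F_Vb_2"] == pytest.approx(12.0, abs=1.0)

    def test_motionless_trial_all_features_near_zero(self):
        seq = simulate_trial(PatientProfile(ability=0.0, seed=5), "T2")
        with pytest.warns(UserWarning, match="flat"):
            fv = extract_features(lowpass_filter(seq), "T2")
        assert fv["F_Va"] < 2.0
        for k in ("F_M_6", "F_M_7", "F_M_8", "F_M_9"):
            assert fv[k] == pytest.approx(0.0, abs=0.5)

    def test_rigid_motion_invariance(self, clean_trials):
        """Angle features depend only on relative landmark geometry."""
        R = _rodrigues(np.array([1.0, 2.0, 0.5]), 37.0)
        shift = np.array([0.3, -1.0, 2.0])
        for tid in ("T1", "T2", "T3"):
            seq = lowpass_filter(clean_trials[tid])
            fv = extract_features(seq, tid)
            fv2 = extract_features(_rigidly_transform(seq, R, shift), tid)
            for k in fv.values:
                assert fv2[k] == pytest.approx(fv[k], abs=1e-6)

    def test_missing_landmark_named(self, clean_trials):
        seq = clean_trials["T1"]
        from fmca import SkeletonSequence
        keep = [lm for lm in seq.landmarks if lm != "wrist_right"]
        idx = [seq.landmarks.index(lm) for lm in keep]
        cut = SkeletonSequence(t=seq.t, landmarks=keep,
                               positions=seq.positions[:, idx, :],
                               side=seq.side)
        with pytest.raises(KeyError, match="wrist_right"):
            extract_features(cut, "T1")

    def test_unknown_test_rejected(self, clean_trials):
        with pytest.raises(ValueError, match="test_id"):
            extract_features(clean_trials["T1"], "T9")
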