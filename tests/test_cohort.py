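"""Synthetic cohort generator: trajectory shape, sensor physics, determinism."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wristpose.cohort import (
    AngleTrace,
    SimConfig,
    TaskProfile,
    _simulate_kinematics,
    forward_model,
    generate_cohort,
    simulate_angle_trajectory,
)

QUIET = SimConfig(
    seed=0, gyro_noise_sd=0.0, acc_noise_sd=0.0, misalignment_sd_deg=0.0,
    forearm_angle_sd_deg=0.0, forearm_pos_sd_m=0.0,
)


class TestAngleTrajectory:
    def test_sixty_seconds_gives_6000_samples_without_sweeps(self):
        cfg = SimConfig(include_sweeps=False)
        tr = simulate_angle_trajectory("assembly", 60.0, np.random.default_rng(0), cfg)
        assert len(tr) == 6000

    def test_sweeps_extend_the_recording_and_cover_extremes(self):
        cfg = SimConfig()
        tr = simulate_angle_trajectory("typing", 60.0, np.random.default_rng(0), cfg)
        assert len(tr) > 6000
        # the scripted sweeps must reach well past the task's dwell range
        assert tr.theta_fe.max() > 45.0 and tr.theta_fe.min() < -45.0

    def test_constant_neutral_profile_is_identically_zero(self):
        prof = TaskProfile(
            fe_mean=0.0, fe_sd=0.0, ru_mean=0.0, ru_sd=0.0, ps_mean=0.0, ps_sd=0.0,
            excursion_rate_hz=0.0,
        )
        cfg = SimConfig(task_profiles={"flat": prof}, include_sweeps=False)
        tr = simulate_angle_trajectory("flat", 30.0, np.random.default_rng(0), cfg)
        assert np.allclose(tr.theta_fe, 0.0, atol=1e-9)

    def test_unknown_task_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="unknown task"):
            simulate_angle_trajectory("welding", 30.0, np.random.default_rng(0))

    def test_physiological_clamps_hold(self):
        cfg = SimConfig(seed=3)
        for task in ("assembly", "checkout", "typing"):
            tr = simulate_angle_trajectory(task, 120.0, np.random.default_rng(3), cfg)
            tr.validate()  # raises if any channel exceeds its clamp

    def test_trajectory_is_band_limited(self):
        """Negligible spectral mass above 5 Hz."""
        tr = simulate_angle_trajectory("checkout", 60.0, np.random.default_rng(1))
        f = np.fft.rfftfreq(len(tr), d=0.01)
        spec = np.abs(np.fft.rfft(tr.theta_fe - tr.theta_fe.mean())) ** 2
        assert spec[f > 5.0].sum() < 1e-3 * spec.sum()


class TestForwardModel:
    @staticmethod
    def _static(fe=0.0, ru=0.0, ps=0.0, n=600):
        return AngleTrace(
            theta_fe=np.full(n, fe), theta_ru=np.full(n, ru), theta_ps=np.full(n, ps)
        )

    def test_static_posture_zero_noise_gyros_are_zero(self):
        imu = forward_model(self._static(fe=20, ru=5, ps=-30), QUIET,
                            np.random.default_rng(0))
        gyro = imu.data[np.r_[3:6, 9:12]]
        assert np.allclose(gyro, 0.0, atol=1e-9)

    def test_static_posture_accelerometer_norm_is_gravity(self):
        imu = forward_model(self._static(fe=35, ru=-8, ps=10), QUIET,
                            np.random.default_rng(0))
        for block in (imu.data[0:3], imu.data[6:9]):
            norms = np.linalg.norm(block, axis=0)
            assert np.allclose(norms, 9.81, atol=1e-9)

    def test_fe_ramp_reads_on_hand_gyro_fe_axis(self):
        """Constant 30 deg/s flexion ramp with a stationary forearm puts
        30 deg/s on the hand gyro's FE (y) axis and ~0 elsewhere."""
        n = 300
        fe = -44.0 + 0.3 * np.arange(n)  # 30 deg/s at 100 Hz, stays within +/-90
        tr = AngleTrace(theta_fe=fe, theta_ru=np.zeros(n), theta_ps=np.zeros(n))
        imu = forward_model(tr, QUIET, np.random.default_rng(0))
        hand_gyro = imu.data[3:6]
        interior = slice(5, -5)  # edge samples suffer one-sided differences
        assert np.allclose(hand_gyro[1, interior], 30.0, atol=0.1)
        assert np.allclose(hand_gyro[0, interior], 0.0, atol=0.1)
        assert np.allclose(hand_gyro[2, interior], 0.0, atol=0.1)

    def test_gyro_matches_quaternion_differentiation_oracle(self):
        """Independent check: body rates recovered from the simulated hand
        orientation by quaternion finite differencing match the analytic
        gyro channels on a noise-free trace."""
        cfg = SimConfig(seed=5, gyro_noise_sd=0.0, acc_noise_sd=0.0,
                        misalignment_sd_deg=0.0)
        tr = simulate_angle_trajectory("assembly", 30.0, np.random.default_rng(5), cfg)
        kin = _simulate_kinematics(tr, cfg, np.random.default_rng(6))
        rot = Rotation.from_matrix(kin.R_hand)
        fs = 100.0
        # central difference of orientation: delta = R[i-1]^-1 R[i+1] over 2 dt
        delta = (rot[:-2].inv() * rot[2:]).as_rotvec() * fs / 2.0
        err = np.rad2deg(np.abs(delta - kin.omega_hand[1:-1]))
        assert err.max() < 1.0          # worst truncation error, deg/s
        assert np.percentile(err, 99) < 0.1

    def test_misalignment_rotates_but_preserves_gravity_norm(self):
        cfg = SimConfig(seed=2, gyro_noise_sd=0.0, acc_noise_sd=0.0,
                        misalignment_sd_deg=0.0, forearm_angle_sd_deg=0.0,
                        forearm_pos_sd_m=0.0)
        mis = Rotation.from_euler("XYZ", [10, -7, 4], degrees=True).as_matrix()
        imu = forward_model(self._static(), cfg, np.random.default_rng(0),
                            misalign_hand=mis, misalign_wrist=mis)
        assert np.allclose(np.linalg.norm(imu.data[0:3], axis=0), 9.81, atol=1e-9)
        # reading must differ from the aligned case
        aligned = forward_model(self._static(), cfg, np.random.default_rng(0))
        assert not np.allclose(imu.data[0:3], aligned.data[0:3], atol=1e-3)


class TestCohort:
    def test_full_design_counts(self, tiny_cohort):
        assert len(tiny_cohort) == 12  # 2 sessions x 2 repetitions x 3 tasks
        metas = {(r.meta.session, r.meta.repetition, r.meta.task) for r in tiny_cohort}
        assert len(metas) == 12

    def test_ten_participants_give_120_recordings(self):
        sim = SimConfig(seed=1, duration_s={t: 6.0 for t in ("assembly", "checkout", "typing")},
                        include_sweeps=False)
        recs = generate_cohort(10, sim)
        assert len(recs) == 120
        assert len({r.meta.participant_id for r in recs}) == 10

    def test_same_seed_is_bit_identical(self):
        sim = SimConfig(seed=42, duration_s={t: 8.0 for t in ("assembly", "checkout", "typing")})
        a = generate_cohort(1, sim)
        b = generate_cohort(1, sim)
        for ra, rb in zip(a, b):
            assert ra.meta == rb.meta
            np.testing.assert_array_equal(ra.angles.theta_fe, rb.angles.theta_fe)
            np.testing.assert_array_equal(ra.imu.data, rb.imu.data)

    def test_angles_and_imu_are_sample_aligned(self, tiny_cohort):
        for rec in tiny_cohort:
            assert len(rec.angles) == len(rec.imu)
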