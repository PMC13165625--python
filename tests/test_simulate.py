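"""Synthetic trajectory and IF-cube generator."""

import dataclasses

import numpy as np
import pytest

import stsradar as sr
from tests.conftest import naive_dft


class TestConstantSpeedTrajectory:
    def test_bounds_plateaus_and_landmark_counts(self, fast_recording, dt):
        trajectory, gt = fast_recording
        assert trajectory.min() == pytest.approx(0.80)
        assert trajectory.max() == pytest.approx(1.10)
        assert gt.n_cycles == 30
        # programmed active duration: first rise to last settle + lead-in phase
        active = gt.settle_times_s[-1] - 2.0  # lead-in is 2 s
        assert active == pytest.approx(30 * 8.0, rel=1e-3)
        # landmark ordering is strictly increasing within and across cycles
        merged = np.stack(
            [gt.begin_rise_times_s, gt.fully_standing_times_s, gt.settle_times_s]
        ).T.ravel()
        assert np.all(np.diff(merged) > 0)

    def test_excursion_equals_programmed_displacement(self, dt):
        spec = sr.speed_protocol(8.0, n_cycles=3)
        trajectory, _ = sr.build_sts_trajectory(spec, dt)
        assert trajectory.max() - trajectory.min() == pytest.approx(0.30)

    def test_plateaus_are_flat_and_transitions_monotone(self, dt):
        spec = sr.speed_protocol(8.0, n_cycles=2)
        trajectory, gt = sr.build_sts_trajectory(spec, dt)
        i_rise = round(gt.begin_rise_times_s[0] / dt)
        i_stand = round(gt.fully_standing_times_s[0] / dt)
        assert np.ptp(trajectory[: i_rise]) == 0.0  # lead-in + seated plateau
        down = trajectory[i_rise : i_stand + 1]
        assert np.all(np.diff(down) <= 0) and down[0] > down[-1]

    def test_zero_cycles_gives_constant_seated_trajectory(self, dt):
        spec = sr.speed_protocol(8.0, n_cycles=0)
        trajectory, gt = sr.build_sts_trajectory(spec, dt)
        assert gt.n_cycles == 0
        assert np.all(trajectory == 1.10)

    def test_linear_shape_and_phase_sum_validation(self, dt):
        spec = sr.speed_protocol(8.0, n_cycles=1, transition_shape="linear")
        trajectory, gt = sr.build_sts_trajectory(spec, dt)
        i0 = round(gt.begin_rise_times_s[0] / dt)
        i1 = round(gt.fully_standing_times_s[0] / dt)
        # linear descent: second differences vanish
        assert np.allclose(np.diff(trajectory[i0:i1], n=2), 0.0, atol=1e-12)
        with pytest.raises(sr.SpecError):
            sr.build_sts_trajectory(
                dataclasses.replace(spec, cycle_duration_s=9.0), dt
            )

    def test_projection_scales_excursion_about_midpoint(self, dt):
        base = sr.speed_protocol(8.0, n_cycles=3)
        t1, gt1 = sr.build_sts_trajectory(base, dt)
        p = 0.6
        t2, gt2 = sr.build_sts_trajectory(
            dataclasses.replace(base, radial_projection_factor=p), dt
        )
        assert t2.max() - t2.min() == pytest.approx(p * (t1.max() - t1.min()))
        mid = 0.5 * (t1.max() + t1.min())
        np.testing.assert_allclose(t2, mid + p * (t1 - mid), atol=1e-12)
        np.testing.assert_allclose(gt2.settle_times_s, gt1.settle_times_s)


class TestMixedSpeedTrajectory:
    def test_sequence_totals_and_macro_period(self, dt):
        spec = sr.mixed_speed_protocol(n_repeats=10, tempo_drift_frac=0.0)
        trajectory, gt = sr.build_mixed_speed_trajectory(spec, dt)
        assert gt.n_cycles == 30
        assert gt.settle_times_s[-1] - 2.0 == pytest.approx(70.0, rel=1e-3)
        assert gt.cycle_durations_s.reshape(10, 3).sum(axis=1) == pytest.approx(7.0)
        other = sr.mixed_speed_protocol((2.0, 2.0, 4.0), n_repeats=5, tempo_drift_frac=0.0)
        _, gt8 = sr.build_mixed_speed_trajectory(other, dt)
        assert gt8.cycle_durations_s.reshape(5, 3).sum(axis=1) == pytest.approx(8.0)

    def test_identical_durations_reduce_to_constant_speed(self, dt):
        mixed = sr.mixed_speed_protocol((8.0, 8.0, 8.0), n_repeats=2, tempo_drift_frac=0.0)
        t_mixed, _ = sr.build_mixed_speed_trajectory(mixed, dt)
        const = sr.TrajectorySpec(
            n_cycles=6, sit_plateau_s=0.0, sit_to_stand_s=4.0,
            stand_plateau_s=0.0, stand_to_sit_s=4.0,
        )
        t_const, _ = sr.build_sts_trajectory(const, dt)
        np.testing.assert_allclose(t_mixed, t_const, atol=1e-12)

    def test_speed_capped_cycles_have_reduced_excursion(self, dt):
        spec = sr.mixed_speed_protocol(n_repeats=2, tempo_drift_frac=0.0)
        _, gt = sr.build_mixed_speed_trajectory(spec, dt)
        # mean phase speed cap 0.15 m/s: 0.5 s / 1 s phases cannot span 0.30 m
        np.testing.assert_allclose(
            gt.cycle_amplitudes_m.reshape(2, 3), [[0.075, 0.15, 0.30]] * 2
        )

    def test_invalid_durations_rejected(self, dt):
        with pytest.raises(sr.SpecError):
            sr.build_mixed_speed_trajectory(
                sr.TrajectorySpec(cycle_durations_s=(1.0, -2.0)), dt
            )
        with pytest.raises(sr.SpecError):
            sr.build_mixed_speed_trajectory(sr.TrajectorySpec(cycle_durations_s=()), dt)


class TestRocking:
    def test_programmed_rocking_span_and_peaks(self, dt):
        rock = sr.RockingSpec(n_oscillations=3, amplitude_m=0.12, oscillation_period_s=0.8)
        spec = sr.rocking_protocol(n_cycles=4, rocking=rock)
        trajectory, gt = sr.build_sts_trajectory(spec, dt)
        assert len(gt.rocking_peak_times_s) == 4
        for peaks in gt.rocking_peak_times_s:
            assert len(peaks) == 4  # settle + 3 rocks
            assert peaks[-1] - peaks[0] == pytest.approx(2.4, abs=2 * dt)
        # dips reach r_sit - amplitude on the seated plateau
        assert trajectory.max() == pytest.approx(1.10)
        i0 = round(gt.rocking_peak_times_s[0][0] / dt)
        i1 = round(gt.begin_rise_times_s[0] / dt)
        assert trajectory[i0:i1].min() == pytest.approx(1.10 - 0.12, abs=1e-6)

    def test_zero_oscillations_and_zero_amplitude_are_identity(self, dt):
        base = sr.speed_protocol(8.0, n_cycles=2)
        trajectory, gt = sr.build_sts_trajectory(base, dt)
        for rock in (
            sr.RockingSpec(n_oscillations=0),
            sr.RockingSpec(n_oscillations=2, amplitude_m=0.0),
        ):
            out, _ = sr.add_rocking(trajectory, gt, rock)
            np.testing.assert_array_equal(out, trajectory)

    def test_invalid_rocking_rejected(self, dt):
        base = sr.speed_protocol(8.0, n_cycles=2)
        trajectory, gt = sr.build_sts_trajectory(base, dt)
        with pytest.raises(sr.SpecError):  # period under 4 slow-time samples
            sr.add_rocking(trajectory, gt, sr.RockingSpec(oscillation_period_s=3 * dt))
        with pytest.raises(sr.SpecError):  # amplitude exceeds excursion
            sr.add_rocking(trajectory, gt, sr.RockingSpec(amplitude_m=0.35))
        with pytest.raises(sr.SpecError):  # span exceeds the seated plateau
            sr.add_rocking(
                trajectory, gt, sr.RockingSpec(n_oscillations=10, oscillation_period_s=0.8)
            )


class TestIFCubeSynthesis:
    def test_static_scatterer_lands_in_predicted_bin(self, config, derived):
        """A 1.00 m reflector peaks at round(R / bin spacing) per the beat-frequency law."""
        trajectory = np.full(4 * config.chirps_per_frame, 1.00)
        scene = sr.SceneSpec(snr_db=None)
        cube = sr.synthesize_if_cube(trajectory, scene, config)
        rti = sr.rti_from_cube(cube)
        expected_bin = round(1.00 / derived.range_bin_spacing_m)
        assert expected_bin == 37
        assert np.all(np.argmax(rti.intensity_db, axis=1) == expected_bin)

    def test_matches_naive_dft_oracle(self, config):
        rng = np.random.default_rng(7)
        trajectory = rng.uniform(0.5, 1.5, config.chirps_per_frame)
        cube = sr.synthesize_if_cube(trajectory, sr.SceneSpec(snr_db=None), config)
        matrix, _ = sr.to_slow_time(sr.average_channels(cube), config)
        fast = sr.range_fft(matrix[:16], config)
        from scipy.signal.windows import blackman

        oracle = naive_dft(matrix[:16], blackman(64, sym=False), 64)
        assert np.max(np.abs(fast - oracle)) / np.max(np.abs(oracle)) < 1e-9

    def test_seed_reproducibility(self, config):
        trajectory = np.full(2 * config.chirps_per_frame, 1.0)
        scene = sr.SceneSpec(snr_db=10.0, rng_seed=42)
        a = sr.synthesize_if_cube(trajectory, scene, config)
        b = sr.synthesize_if_cube(trajectory, scene, config)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = sr.synthesize_if_cube(
            trajectory, dataclasses.replace(scene, rng_seed=43), config
        )
        assert not np.array_equal(a.samples, c.samples)

    def test_channel_averaging_reproduces_single_channel(self, config):
        """Identical signal on all channels with zero offsets: mean is a no-op."""
        trajectory = np.full(config.chirps_per_frame, 0.9)
        cube = sr.synthesize_if_cube(trajectory, sr.SceneSpec(snr_db=None), config)
        averaged = sr.average_channels(cube)
        np.testing.assert_allclose(averaged, cube.samples[:, 0], atol=1e-7)

    def test_zero_amplitude_scene_is_pure_noise(self, config):
        trajectory = np.full(2 * config.chirps_per_frame, 1.0)
        scene = sr.SceneSpec(torso_amplitude=0.0, snr_db=20.0, rng_seed=3)
        cube = sr.synthesize_if_cube(trajectory, scene, config)
        assert np.std(cube.samples) > 0
        rti = sr.rti_from_cube(cube)
        # no persistent ridge: the argmax bin wanders across snapshots
        assert len(np.unique(np.argmax(rti.intensity_db, axis=1))) > 10

    def test_out_of_range_scatterers_rejected(self, config, derived):
        too_far = np.full(config.chirps_per_frame, derived.max_range_m + 0.1)
        with pytest.raises(sr.SpecError):
            sr.synthesize_if_cube(too_far, sr.SceneSpec(), config)
        ok = np.full(config.chirps_per_frame, 1.0)
        with pytest.raises(sr.SpecError):
            sr.synthesize_if_cube(
                ok, sr.SceneSpec(static_clutter=((2.5, 1.0),)), config
            )

    def test_real_mode_cube_is_real_valued(self, config):
        # real mode halves the unambiguous range (33 bins, ~0.9 m)
        real_cfg = dataclasses.replace(config, sampling_mode="real")
        trajectory = np.full(config.chirps_per_frame, 0.7)
        cube = sr.synthesize_if_cube(trajectory, sr.SceneSpec(snr_db=None), real_cfg)
        assert not np.iscomplexobj(cube.samples)
        rti = sr.rti_from_cube(cube)
        assert rti.intensity_db.shape[1] == 33
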