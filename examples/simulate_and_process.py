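"""Full pipeline on a synthetic noisy recording.

Synthesizes raw IF data for six fast sit-to-stand cycles (plus static
clutter at 0.5 m and 10 dB SNR), forms the clutter-filtered range-time
intensity map, tracks and smooths the torso trajectory, detects the
seated-edge / standing-valley landmarks, and prints the per-condition
feature summary. Mean cycle duration should recover the programmed 8 s;
displacements measure the excursion between the standing valley and the
seated detection threshold (~0.27 m of the programmed 0.30 m).
"""

import stsradar as sr

config = sr.default_config()
derived = sr.derive_radar_parameters(config)

spec = sr.speed_protocol(cycle_duration_s=8.0, n_cycles=6)
trajectory, truth = sr.build_sts_trajectory(spec, derived.slow_time_step_s)

scene = sr.SceneSpec(snr_db=10.0, static_clutter=((0.5, 0.8),), rng_seed=1)
cube = sr.synthesize_if_cube(trajectory, scene, config)
print(f"IF cube: {cube.samples.shape} (frame, channel, chirp, sample)")

result = sr.run_pipeline(cube, condition="fast")
print(f"detected {result.events.n_cycles} cycles "
      f"(programmed {truth.n_cycles})")
print(f"dominant cadence: {result.spectral.f_peak_hz:.4f} Hz "
      f"(programmed 1/8 s = 0.1250 Hz)")
print()
print(result.summary.to_string(index=False))
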