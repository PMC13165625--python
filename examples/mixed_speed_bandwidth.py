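"""Spectral signature of speed-variability (mixed fast/normal/slow) execution.

A recording that repeats 1 s, 2 s, and 4 s cycles has a 7 s macro-period:
the dominant spectral peak sits at its reciprocal, and because the execution
is irregular (tempo drift, repetition jitter) the half-power bandwidth is
wider than for any constant-speed recording — a compact marker of
cycle-to-cycle variability.
"""

import stsradar as sr

derived = sr.derive_radar_parameters(sr.default_config())
dt = derived.slow_time_step_s

print(f"{'condition':<10} {'f_peak [Hz]':>11} {'period [s]':>10} {'BW_3dB [Hz]':>12}")
for name, cycle_s, n in (("fast", 8.0, 30), ("medium", 14.0, 17), ("slow", 24.0, 10)):
    spec = sr.speed_protocol(cycle_s, n_cycles=n, cycle_jitter_s=0.3, rng_seed=1)
    trajectory, _ = sr.build_sts_trajectory(spec, dt)
    sf = sr.spectral_features(trajectory, dt)
    print(f"{name:<10} {sf.f_peak_hz:>11.4f} {sf.cycle_period_s:>10.2f} {sf.bw_3db_hz:>12.5f}")

spec = sr.mixed_speed_protocol(n_repeats=34, cycle_jitter_s=0.3, rng_seed=1)
trajectory, _ = sr.build_mixed_speed_trajectory(spec, dt)
sf = sr.spectral_features(trajectory, dt)
print(f"{'mixed':<10} {sf.f_peak_hz:>11.4f} {sf.cycle_period_s:>10.2f} {sf.bw_3db_hz:>12.5f}")

print()
print("The mixed recording's dominant period matches the 1+2+4 s pattern's")
print("macro-period, and its bandwidth exceeds every constant-speed trial.")
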