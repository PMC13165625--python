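"""Derived physical quantities of the 60 GHz FMCW configuration.

The 5.5 GHz sweep sets the range-bin spacing c/(2B); the 64 retained
complex-baseband bins set the unambiguous range; the hardware chirp interval
sets the unambiguous radial velocity; and the frame time divided by the
chirps per frame gives the uniform slow-time step of the range-time map.
"""

import stsradar as sr

config = sr.default_config()
derived = sr.derive_radar_parameters(config)

print(f"bandwidth           : {config.bandwidth_hz / 1e9:.1f} GHz")
print(f"chirp slope         : {derived.chirp_slope_hz_per_s:.4g} Hz/s")
print(f"range bin spacing   : {derived.range_bin_spacing_m * 100:.2f} cm")
print(f"max unambiguous range: {derived.max_range_m:.2f} m")
print(f"max radial velocity : {derived.max_velocity_mps:.2f} m/s")
print(f"slow-time step      : {derived.slow_time_step_s * 1e3:.3f} ms "
      f"({1 / derived.slow_time_step_s:.0f} snapshots/s)")
print()
print("A seated-to-standing torso displacement of ~0.3 m therefore spans")
print(f"~{0.3 / derived.range_bin_spacing_m:.0f} range bins, and a 24 s cycle "
      f"covers ~{24 / derived.slow_time_step_s:.0f} slow-time snapshots.")
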