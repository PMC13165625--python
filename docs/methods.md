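# Methods

This note documents the models, parameter choices, and numerical decisions
behind `stsradar`, and what the synthetic studies do and do not demonstrate
about real radar data.

## Radar model and derived quantities

The sensor model is a linear-FMCW radar: a chirp sweeping bandwidth
`B = f_end − f_start` over the ADC acquisition window `T_ADC = N / f_s`
(slope `S = B / T_ADC`), repeated `M` times per frame on `C` receive
channels. A point reflector at range `R` produces a beat tone
`f_b = 2SR/c`, so FFT bin spacing maps to range spacing
`ΔR = c (f_s / N_fft) / 2S`, equal to the classical resolution `c / 2B`
without zero padding. The bundled default configuration (58–63.5 GHz,
64 × 64 samples/chirps, 2 MHz ADC, 77.27 ms frames, 3 RX channels) yields
ΔR ≈ 0.0273 m, 64-bin unambiguous range ≈ 1.74 m, center wavelength
4.93 mm, and unambiguous velocity `λc / 4T_chirp` ≈ 2.09 m/s.

Two decisions worth flagging:

* **Sampling mode.** With 64 *real* samples a one-sided FFT keeps 33 bins
  (≈0.9 m unambiguous range); the reference parameter sheet's 1.75 m is
  only consistent with *complex* baseband (all 64 bins). Complex is
  therefore the default; real mode is supported with the halved range.
* **Two chirp intervals.** The hardware chirp repetition interval
  (0.591 ms) governs the velocity ambiguity; the uniform slow-time step of
  the RTI map is `T_frame / M ≈ 1.207 ms` (chirps treated as uniformly
  spaced in the frame). They are carried separately and never interchanged.

## Scene simulator

The torso is a single dominant point reflector whose range alternates
between a seated plateau (`R_sit`, default 1.10 m) and a standing level
(`R_stand`, default 0.80 m; excursion 0.30 m, inside the plausible band of
real torso displacements and well under the unambiguous range). Transitions
are raised-cosine by default — continuous velocity with peak `πD/2T` — with
a linear option kept for closed-form tests. The IF synthesis places, per
snapshot and channel, `Σ_s A_s exp(j(2π f_b,s k/f_s + 4π R_s/λc + φ_c))`
plus white Gaussian noise at a configurable SNR relative to the torso echo
power (default 20 dB; a zero-amplitude scene falls back to unit-referenced
noise). Everything is deterministic given the scene seed.

**Constant-speed protocols.** A full cycle is split 45% seated plateau, 25%
sit-to-stand transition, 5% standing plateau, 25% stand-to-sit transition.
For the standard 24 / 14 / 8 s protocols this gives 6 / 3.5 / 2 s
transitions and detected phase durations in the range observed in real
recordings (short standing dwell, long seated rest).

**Physiological speed cap.** Transition phases execute at a mean radial
speed of at most 0.15 m/s (default), chosen inside the 0.13–0.24 m/s band
that real torso tracking reports across slow-to-fast executions. The cap is
inactive for all constant-speed protocols (their transitions are ≥ 2 s) but
limits the excursion of sub-4 s cycles in the mixed-speed condition. This
matters structurally: for equal-amplitude concatenated 1 + 2 + 4 s cycles
the *second* harmonic of the 7 s macro-period dominates the spectrum (the
normal and slow sub-cycles interfere destructively at the fundamental), and
only with speed-limited — hence amplitude-reduced — fast and normal
sub-cycles does the dominant spectral period land on the macro-period, as
observed in real mixed-speed trials (which also show the corresponding
amplitude fluctuations).

**Execution variability.** Two optional components model unpaced human
timing: independent Gaussian cycle-duration jitter (`cycle_jitter_s`,
default 0; studies use 0.3 s, matching the repetition variability of real
fast-protocol recordings) and a deterministic linear tempo drift
(`tempo_drift_frac`; the mixed-speed protocol defaults to 8% across the
recording). Perfectly periodic noiseless recordings have a half-power
bandwidth fixed by the observation window (≈ 0.886 / T_obs) regardless of
condition, so bandwidth as a *regularity* marker only exists with
variability present; with these defaults the mixed-speed bandwidth
(~0.005–0.013 Hz) exceeds every constant-speed trial's, consistent with the
~2× spread seen in real data.

**Rocking.** Preparatory rocking replaces the last `n · P` seconds of the
seated plateau before each rise with cosine dips of amplitude `a` (defaults
n = 3, P = 0.8 s, a = 0.12 m), producing n + 1 seated peaks spanning `n·P`.
The rocking protocol makes the rocking span the whole seated plateau, as in
real rocking trials where oscillation immediately precedes the rise.

**Side-facing geometry** is emulated by a radial projection factor
p ∈ (0, 1] scaling the excursion about its midpoint; it scales
displacements and velocities exactly by p and leaves all timings unchanged.

**Not modeled:** limb micro-Doppler, body occlusion/shadowing, antenna
patterns, multipath, multi-person scenes. Passing tests demonstrate the
pipeline's correctness on a single-dominant-reflector scene with additive
noise and static clutter — not robustness to the full complexity of real
indoor recordings.

## Trajectory extraction

Argmax tracking excludes bin 0 (DC / ground clutter) by default and breaks
intensity ties toward the nearer bin. Migration suppression clamps
single-snapshot jumps above `2ΔR ≈ 5.5 cm` — at realistic torso speeds
(≤ 0.4 m/s) true motion per 1.2 ms snapshot is far below one bin — and is
idempotent. Smoothing uses a Savitzky–Golay filter, window 1001 samples
(≈ 1.2 s) and order 3; boundary samples use scipy's polynomial-fit edge
treatment, which preserves cubic trends exactly over the full track (mirror
reflection would distort odd polynomials at the edges). A frame-level mode
keeps one snapshot per 77 ms frame and rescales the window to the nearest
odd count preserving ≈ 1.2 s of support.

## Event detection

The dual thresholds are placed by a span-quantile rule: with robust extrema
(1st/99th percentiles) and margin q, `θ_sit` sits q below the top of the
span and `θ_stand` q above the bottom. The default margin is q = 0.1: the
displacement features evaluate the trajectory *at* the θ_sit crossing, so a
measured ascent displacement is ≈ (1−q) of the true excursion, and q = 0.1
keeps it within two range bins of the programmed 0.30 m (and inside the
0.27–0.33 m band reported for real recordings). Both thresholds are
user-overridable.

Seated plateaus are maximal excursions above θ_sit lasting ≥ 0.25 s
(shorter blips are threshold chatter); consecutive plateaus with no dip
below θ_stand between them are merged, so each inter-plateau gap contains
exactly one standing valley (the first range minimum on ties). A plateau
touching the first or last sample has an undefined outer edge — the
recording started or ended mid-plateau — reported as NaN; features needing
that landmark skip those cycles. This also excludes the preparation period
before the first complete cycle.

For rocking trials, valleys are detected directly as minima of
sub-θ_stand excursions and seated peaks with `scipy.signal.find_peaks`
between consecutive valleys. The peak height gate is the *midpoint*
(θ_sit + θ_stand)/2 rather than θ_sit: the 1001-sample smoother passes only
~28% of a 0.8 s rocking oscillation, placing smoothed seated peaks a few
centimetres below a threshold at 90% of span while still far above the
standing level. A prominence floor of 5% of the inter-threshold distance
rejects numerical ripple on flat plateaus; peaks closer than 0.4 s merge,
keeping the higher.

## Feature conventions

"Ascent" and "descent" name the range-*increasing* (standing valley → next
seated settle) and range-*decreasing* (begin-rise → valley) trajectory
phases. For a subject-facing radar the body motion that *decreases* torso
range is standing up; the landmark algebra
(`T_ascent,i = t_le,i+1 − t_v,i`, positive displacements on ascent) is the
self-consistent reading of the event framework and is used throughout, with
this naming caveat stated once here. The rocking identity
`T_stand = T_rock + T_ascent` holds exactly by construction per cycle;
note that *averages* of these quantities over different cycle subsets need
not satisfy the identity.

The velocity ratio is computed on magnitudes (`|v̄_asc| / |v̄_desc|`), so
symmetric executions give 1 regardless of sign conventions. Velocities come
from `numpy.gradient` (central differences, one-sided ends) on the smoothed
track with no re-smoothing; peak velocities are extrema over the closed
phase window.

Spectral features remove the trajectory mean (the raw signal is
DC-dominated), zero-pad to at least 4× the signal length (next power of
two) so the half-power crossings can be linearly interpolated on a fine
grid, and search 0.01–2 Hz by default (excluding DC and sub-cm/s drift). A
side whose magnitude never falls below peak/√2 inside the band is clamped
to the band edge and flagged.

Summaries report per-feature sample mean and standard deviation (n − 1
denominator), skipping NaN landmarks and cycles flagged invalid; a
single-cycle feature reports std 0 with n = 1.

## Numerical choices

* log-power floor ε = 10⁻¹² inside `10 log10(|X|² + ε)`.
* Clutter removal subtracts the slow-time complex mean per range bin in the
  linear domain before the log (zero-Doppler notch); a moving-average MTI
  alternative is available. A single-snapshot input passes through with a
  warning.
* FFT length defaults to N (no padding), so `ΔR = c/2B` exactly; padding is
  exposed and refines the grid without changing resolution.
* No window normalization: absolute dB values are never compared across
  implementations.
* Degenerate inputs raise typed errors: flat tracks ("no STS motion"),
  tracks never crossing a threshold ("no cycles"), malformed containers
  (format errors with expected-vs-found counts), inconsistent scene specs.

## Verification problem sizes

The test suite exercises noiseless parameter recovery on full 30-cycle
recordings at trajectory level (24 / 14 / 8 s protocols; mean cycle
duration within 2%), and noisy end-to-end recovery through full IF-cube
synthesis at 10 dB SNR with 4 / 5 / 6 cycles per speed over five seeds
(within 5%). Oracle checks compare the range FFT against a brute-force
O(N²) DFT on ≤ 32-snapshot cubes and landmark detection against the
generator's analytic threshold-crossing times. These sizes were chosen as
the smallest that leave each estimate's sampling error well below the
tolerance it is tested against.

## Known limitations

* Single dominant reflector: no occlusion, shadowing, or multi-scatterer
  torso model; the knee push-off condition adds a hands reflector for
  qualitative RTI broadening only, with no quantitative claims.
* The migration threshold, plateau minimum, peak-separation, and threshold
  margin are fixed defaults, not adaptively estimated.
* Timing variability is modeled as per-cycle scaling (jitter + linear
  drift); real executions vary phase composition within cycles too.
* Frame-level mode decimates after tracking; it does not re-run detection
  at frame rate on raw frame profiles.
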