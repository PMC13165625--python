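"""Synthetic sit-to-stand scenes: ground-truth trajectories and raw IF cubes.

The torso is modeled as a single dominant reflector whose radial range
alternates between a seated plateau (maximum range) and a standing valley
(minimum range), with raised-cosine (default) or linear transitions. The
generator also supports a repeating mixed-speed cycle sequence, preparatory
rocking oscillations on the seated plateau, an optional secondary "hands on
knees" reflector, static clutter, multi-channel reception, and additive
noise, so the whole downstream pipeline can be exercised without hardware.

Physiological scaling: a transition phase of duration T is executed at a mean
radial speed of at most ``mean_phase_speed_limit_mps`` (default 0.15 m/s, in
the middle of the range observed for real torso motion). Cycles too short to
complete the full excursion at that speed are generated with proportionally
reduced excursion; for the standard slow/medium/fast protocols (transition
phases >= 2 s) the cap is inactive and the excursion is the full
``r_sit_m - r_stand_m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import RadarConfig, derive_radar_parameters
from .errors import SpecError
from .rti import IFCube

__all__ = [
    "RockingSpec",
    "HandsSpec",
    "TrajectorySpec",
    "SceneSpec",
    "GroundTruth",
    "build_sts_trajectory",
    "build_mixed_speed_trajectory",
    "add_rocking",
    "synthesize_if_cube",
    "speed_protocol",
    "mixed_speed_protocol",
    "rocking_protocol",
]


@dataclass(frozen=True)
class RockingSpec:
    """Preparatory rocking: forward-backward dips on the seated plateau."""

    n_oscillations: int = 3
    amplitude_m: float = 0.12
    oscillation_period_s: float = 0.8

    @property
    def span_s(self) -> float:
        """Programmed rocking span (first to last seated peak)."""
        return self.n_oscillations * self.oscillation_period_s


@dataclass(frozen=True)
class HandsSpec:
    """Secondary reflector emulating hands placed on the knees.

    Active while the torso is in the seated half of its excursion (seated
    plateaus and the early rising phase), offset toward the radar from the
    torso; produces the broader, more diffuse seated signature characteristic
    of knee push-off. Qualitative only.
    """

    range_offset_m: float = -0.15
    amplitude: float = 0.5


@dataclass(frozen=True)
class TrajectorySpec:
    """Programmed torso trajectory for one recording.

    A cycle is sit plateau -> sit-to-stand transition (range decreasing) ->
    stand plateau -> stand-to-sit transition (range increasing). Defaults
    reproduce the fast constant-speed protocol (8 s full cycle).
    """

    r_sit_m: float = 1.10
    r_stand_m: float = 0.80
    n_cycles: int = 30
    sit_plateau_s: float = 3.6
    sit_to_stand_s: float = 2.0
    stand_plateau_s: float = 0.4
    stand_to_sit_s: float = 2.0
    transition_shape: str = "raised_cosine"
    cycle_duration_s: float | None = None
    cycle_durations_s: tuple[float, ...] | None = None
    rocking: RockingSpec | None = None
    lead_in_s: float = 2.0
    lead_out_s: float = 2.0
    radial_projection_factor: float = 1.0
    mean_phase_speed_limit_mps: float | None = 0.15
    cycle_jitter_s: float = 0.0
    tempo_drift_frac: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if not (self.r_sit_m > self.r_stand_m >= 0.0):
            raise SpecError(f"need r_sit > r_stand >= 0, got {self.r_sit_m}, {self.r_stand_m}")
        if self.n_cycles < 0:
            raise SpecError("n_cycles must be >= 0")
        if self.sit_to_stand_s <= 0 or self.stand_to_sit_s <= 0:
            raise SpecError("transition durations must be positive")
        if self.sit_plateau_s < 0 or self.stand_plateau_s < 0:
            raise SpecError("plateau durations must be non-negative")
        if self.lead_in_s < 0 or self.lead_out_s < 0:
            raise SpecError("lead-in/lead-out must be non-negative")
        if self.transition_shape not in ("raised_cosine", "linear"):
            raise SpecError(f"unknown transition shape {self.transition_shape!r}")
        if not (0.0 < self.radial_projection_factor <= 1.0):
            raise SpecError("radial_projection_factor must be in (0, 1]")
        if self.cycle_duration_s is not None:
            total = (
                self.sit_plateau_s + self.sit_to_stand_s + self.stand_plateau_s + self.stand_to_sit_s
            )
            if not math.isclose(total, self.cycle_duration_s, rel_tol=0, abs_tol=1e-9):
                raise SpecError(
                    f"phase durations sum to {total} s but cycle_duration_s = {self.cycle_duration_s} s"
                )
        if self.cycle_durations_s is not None:
            if len(self.cycle_durations_s) == 0:
                raise SpecError("cycle_durations_s must be non-empty")
            if any(d <= 0 for d in self.cycle_durations_s):
                raise SpecError("all cycle durations must be positive")
        if self.cycle_jitter_s < 0:
            raise SpecError("cycle_jitter_s must be non-negative")
        if not 0.0 <= self.tempo_drift_frac < 1.0:
            raise SpecError("tempo_drift_frac must be in [0, 1)")
        if self.rocking is not None:
            r = self.rocking
            if r.n_oscillations < 0 or r.amplitude_m < 0 or r.oscillation_period_s <= 0:
                raise SpecError("invalid rocking parameters")
            if r.amplitude_m >= self.r_sit_m - self.r_stand_m:
                raise SpecError("rocking amplitude must be smaller than the seated-standing excursion")

    @property
    def excursion_m(self) -> float:
        return self.r_sit_m - self.r_stand_m


@dataclass(frozen=True)
class SceneSpec:
    """Radar scene wrapped around a torso trajectory."""

    torso_amplitude: float = 1.0
    hands: HandsSpec | None = None
    static_clutter: tuple[tuple[float, float], ...] = ()
    snr_db: float | None = 20.0
    channel_phase_offsets_rad: tuple[float, ...] | None = None
    rng_seed: int = 0


@dataclass
class GroundTruth:
    """Construction-time truth used as the oracle for recovery tests.

    Landmarks per cycle i: ``begin_rise`` (sit plateau ends, range starts to
    drop), ``fully_standing`` (range reaches the standing level), ``settle``
    (range is back at the seated level, cycle ends). ``left_edge`` /
    ``right_edge`` predict where the trajectory crosses the seated detection
    threshold placed at ``threshold_quantile`` of the span; they are only
    available when all cycles share one amplitude.
    """

    slow_time_step_s: float
    r_sit_m: float
    r_stand_m: float
    trajectory_m: np.ndarray
    settle_times_s: np.ndarray
    begin_rise_times_s: np.ndarray
    fully_standing_times_s: np.ndarray
    cycle_durations_s: np.ndarray
    cycle_amplitudes_m: np.ndarray
    threshold_quantile: float = 0.1
    left_edge_times_s: np.ndarray | None = None
    right_edge_times_s: np.ndarray | None = None
    rocking_peak_times_s: list[np.ndarray] | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.settle_times_s)


# ---------------------------------------------------------------------------
# trajectory construction


def _transition(n: int, duration_s: float, dt: float, hi: float, lo: float, shape: str, down: bool) -> np.ndarray:
    """Sampled transition between hi and lo, excluding the endpoint sample."""
    tau = np.arange(n) * dt
    if shape == "raised_cosine":
        frac = 0.5 * (1.0 + np.cos(np.pi * tau / duration_s))
    else:  # linear
        frac = 1.0 - tau / duration_s
    if not down:
        frac = 1.0 - frac
    return lo + (hi - lo) * frac


def _crossing_fraction(q: float, shape: str, down: bool) -> float:
    """Fraction of a transition at which the (1-q)-span level is crossed.

    For the descending phase this is the last time above the seated
    threshold; for the ascending phase, the first time above it.
    """
    if shape == "raised_cosine":
        if down:
            return math.acos(1.0 - 2.0 * q) / math.pi
        return math.acos(2.0 * q - 1.0) / math.pi
    return q if down else 1.0 - q


def _phase_amplitude(spec: TrajectorySpec, down_s: float, up_s: float) -> float:
    full = spec.excursion_m
    cap = spec.mean_phase_speed_limit_mps
    if cap is None:
        return full
    return min(full, cap * down_s, cap * up_s)


def _jitter_factors(spec: TrajectorySpec, base_cycle_s: float) -> np.ndarray:
    """Per-cycle duration scale factors for repetition-timing variability.

    Two components of unpaced execution: a deterministic linear tempo drift
    sweeping the duration from (1 - drift) to (1 + drift) of nominal over the
    recording, and an independent additive Gaussian error of std
    ``cycle_jitter_s`` per repetition (truncated so no cycle shrinks below
    20% of nominal). All phases of a cycle scale together.
    """
    n = spec.n_cycles
    d = spec.tempo_drift_frac
    factors = np.linspace(1.0 - d, 1.0 + d, n) if (d > 0 and n > 1) else np.ones(n)
    if spec.cycle_jitter_s > 0.0 and n > 0:
        rng = np.random.default_rng(spec.rng_seed)
        factors = factors + rng.normal(0.0, spec.cycle_jitter_s, n) / base_cycle_s
    return np.clip(factors, 0.2, None)


def build_sts_trajectory(
    spec: TrajectorySpec, slow_time_step_s: float, threshold_quantile: float = 0.1
) -> tuple[np.ndarray, GroundTruth]:
    """Sample a constant-speed sit-to-stand trajectory on the slow-time grid.

    Returns the sampled trajectory and the construction ground truth. With
    ``n_cycles == 0`` the trajectory is constant at the seated range.
    """
    spec.validate()
    if spec.cycle_durations_s is not None:
        return build_mixed_speed_trajectory(spec, slow_time_step_s)
    dt = slow_time_step_s
    if dt <= 0:
        raise SpecError("slow_time_step_s must be positive")

    segments: list[np.ndarray] = []
    n_total = 0

    def emit(arr: np.ndarray) -> None:
        nonlocal n_total
        segments.append(arr)
        n_total += len(arr)

    base_phases = np.array(
        [spec.sit_plateau_s, spec.sit_to_stand_s, spec.stand_plateau_s, spec.stand_to_sit_s]
    )
    base_cycle = float(base_phases.sum())
    factors = _jitter_factors(spec, base_cycle)

    settle, begin_rise, standing = [], [], []
    amps, durations, left_edge_t, right_edge_t = [], [], [], []
    q = threshold_quantile
    fr_down = _crossing_fraction(q, spec.transition_shape, down=True)
    fr_up = _crossing_fraction(q, spec.transition_shape, down=False)

    emit(np.full(round(spec.lead_in_s / dt), spec.r_sit_m))
    for f in factors:
        sit_p, t_down, stand_p, t_up = base_phases * f
        amp = _phase_amplitude(spec, t_down, t_up)
        lo = spec.r_sit_m - amp
        amps.append(amp)
        durations.append(float((base_phases * f).sum()))
        emit(np.full(round(sit_p / dt), spec.r_sit_m))
        begin_rise.append(n_total)
        right_edge_t.append(n_total * dt + fr_down * t_down)
        emit(_transition(round(t_down / dt), t_down, dt, spec.r_sit_m, lo, spec.transition_shape, down=True))
        standing.append(n_total)
        emit(np.full(round(stand_p / dt), lo))
        left_edge_t.append(n_total * dt + fr_up * t_up)
        emit(_transition(round(t_up / dt), t_up, dt, spec.r_sit_m, lo, spec.transition_shape, down=False))
        settle.append(n_total)
    emit(np.full(round(spec.lead_out_s / dt), spec.r_sit_m))

    trajectory = np.concatenate(segments) if segments else np.full(0, spec.r_sit_m)
    if trajectory.size == 0:
        raise SpecError("trajectory has zero samples; durations too short for the slow-time grid")

    amps_arr = np.asarray(amps)
    uniform = amps_arr.size == 0 or np.allclose(amps_arr, amps_arr[0] if amps_arr.size else 0.0)
    gt = GroundTruth(
        slow_time_step_s=dt,
        r_sit_m=spec.r_sit_m,
        r_stand_m=spec.r_sit_m - (amps_arr.max() if amps_arr.size else 0.0),
        trajectory_m=trajectory,
        settle_times_s=np.asarray(settle, dtype=float) * dt,
        begin_rise_times_s=np.asarray(begin_rise, dtype=float) * dt,
        fully_standing_times_s=np.asarray(standing, dtype=float) * dt,
        cycle_durations_s=np.asarray(durations),
        cycle_amplitudes_m=amps_arr,
        threshold_quantile=q,
        left_edge_times_s=np.asarray(left_edge_t) if uniform else None,
        right_edge_times_s=np.asarray(right_edge_t) if uniform else None,
    )

    if spec.rocking is not None and spec.rocking.n_oscillations > 0:
        trajectory, gt = add_rocking(trajectory, gt, spec.rocking)
    if spec.radial_projection_factor != 1.0:
        trajectory, gt = _apply_projection(trajectory, gt, spec.radial_projection_factor)
    return trajectory, gt


def build_mixed_speed_trajectory(
    spec: TrajectorySpec, slow_time_step_s: float
) -> tuple[np.ndarray, GroundTruth]:
    """Concatenate cycles with the per-cycle durations in ``cycle_durations_s``.

    Each cycle is split into a descending and an ascending half (no
    plateaus), matching a continuous down-up execution; the macro-period of
    a repeating sequence is the sum of its durations. Cycles shorter than
    the full excursion allows at the configured mean-speed cap are generated
    with reduced amplitude.
    """
    spec.validate()
    if spec.cycle_durations_s is None:
        raise SpecError("cycle_durations_s is required for a mixed-speed trajectory")
    dt = slow_time_step_s
    if dt <= 0:
        raise SpecError("slow_time_step_s must be positive")

    segments: list[np.ndarray] = []
    n_total = 0

    def emit(arr: np.ndarray) -> None:
        nonlocal n_total
        segments.append(arr)
        n_total += len(arr)

    durations = np.asarray(spec.cycle_durations_s, dtype=float)
    d = spec.tempo_drift_frac
    if d > 0 and durations.size > 1:
        durations = durations * np.linspace(1.0 - d, 1.0 + d, durations.size)
    if spec.cycle_jitter_s > 0.0:
        rng = np.random.default_rng(spec.rng_seed)
        durations = np.clip(
            durations + rng.normal(0.0, spec.cycle_jitter_s, durations.size), 0.2 * durations, None
        )

    settle, begin_rise, standing, amps = [], [], [], []
    emit(np.full(round(spec.lead_in_s / dt), spec.r_sit_m))
    for cyc in durations:
        half = cyc / 2.0
        amp = _phase_amplitude(spec, half, half)
        lo = spec.r_sit_m - amp
        amps.append(amp)
        begin_rise.append(n_total)
        emit(_transition(round(half / dt), half, dt, spec.r_sit_m, lo, spec.transition_shape, down=True))
        standing.append(n_total)
        emit(_transition(round(half / dt), half, dt, spec.r_sit_m, lo, spec.transition_shape, down=False))
        settle.append(n_total)
    emit(np.full(round(spec.lead_out_s / dt), spec.r_sit_m))

    trajectory = np.concatenate(segments)
    amps_arr = np.asarray(amps)
    uniform = bool(amps_arr.size) and np.allclose(amps_arr, amps_arr[0])

    settle_t = np.asarray(settle, dtype=float) * dt
    begin_rise_t = np.asarray(begin_rise, dtype=float) * dt
    standing_t = np.asarray(standing, dtype=float) * dt
    q = 0.1
    left_edge_t = right_edge_t = None
    if uniform:
        halves = durations / 2.0
        right_edge_t = begin_rise_t + _crossing_fraction(q, spec.transition_shape, True) * halves
        left_edge_t = standing_t + _crossing_fraction(q, spec.transition_shape, False) * halves

    gt = GroundTruth(
        slow_time_step_s=dt,
        r_sit_m=spec.r_sit_m,
        r_stand_m=spec.r_sit_m - (amps_arr.max() if amps_arr.size else 0.0),
        trajectory_m=trajectory,
        settle_times_s=settle_t,
        begin_rise_times_s=begin_rise_t,
        fully_standing_times_s=standing_t,
        cycle_durations_s=durations,
        cycle_amplitudes_m=amps_arr,
        threshold_quantile=q,
        left_edge_times_s=left_edge_t,
        right_edge_times_s=right_edge_t,
    )
    if spec.radial_projection_factor != 1.0:
        trajectory, gt = _apply_projection(trajectory, gt, spec.radial_projection_factor)
    return trajectory, gt


def _apply_projection(trajectory: np.ndarray, gt: GroundTruth, p: float) -> tuple[np.ndarray, GroundTruth]:
    """Scale the excursion by p about the trajectory midpoint (side-facing geometry)."""
    mid = 0.5 * (trajectory.max() + trajectory.min())
    projected = mid + p * (trajectory - mid)
    gt = replace(
        gt,
        trajectory_m=projected,
        r_sit_m=mid + p * (gt.r_sit_m - mid),
        r_stand_m=mid + p * (gt.r_stand_m - mid),
        cycle_amplitudes_m=p * gt.cycle_amplitudes_m,
    )
    return projected, gt


def add_rocking(
    trajectory: np.ndarray, gt: GroundTruth, rocking: RockingSpec
) -> tuple[np.ndarray, GroundTruth]:
    """Insert rocking dips on the seated plateau immediately before each rise.

    The final ``n_oscillations * oscillation_period_s`` seconds of each
    seated plateau are replaced by cosine dips of the given amplitude; seated
    peaks (local range maxima at the seated level) then occur at the start of
    the rocking window and after each oscillation, ``n_oscillations + 1``
    peaks spanning ``n_oscillations`` periods. Zero oscillations or zero
    amplitude return the trajectory unchanged.
    """
    if rocking.n_oscillations == 0 or rocking.amplitude_m == 0.0:
        return trajectory, replace(gt, rocking_peak_times_s=None)
    dt = gt.slow_time_step_s
    if rocking.oscillation_period_s < 4 * dt:
        raise SpecError(
            f"rocking period {rocking.oscillation_period_s} s has fewer than 4 samples "
            f"on the slow-time grid (step {dt} s)"
        )
    if rocking.amplitude_m >= gt.r_sit_m - gt.r_stand_m:
        raise SpecError("rocking amplitude must be smaller than the seated-standing excursion")

    out = np.array(trajectory, dtype=float, copy=True)
    span_n = round(rocking.span_s / dt)
    peaks_all: list[np.ndarray] = []
    begin_idx = np.round(gt.begin_rise_times_s / dt).astype(int)
    plateau_start = np.concatenate(([0.0], gt.settle_times_s[:-1]))
    for i, b in enumerate(begin_idx):
        available = gt.begin_rise_times_s[i] - plateau_start[i]
        if rocking.span_s > available + 1e-9:
            raise SpecError(
                f"rocking span {rocking.span_s:.3f} s exceeds the seated plateau "
                f"({available:.3f} s) before cycle {i}"
            )
        start = b - span_n
        tau = np.arange(span_n) * dt
        out[start:b] = gt.r_sit_m - rocking.amplitude_m * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * tau / rocking.oscillation_period_s)
        )
        peaks = start * dt + np.arange(rocking.n_oscillations + 1) * rocking.oscillation_period_s
        peaks_all.append(peaks)
    return out, replace(gt, trajectory_m=out, rocking_peak_times_s=peaks_all)


# ---------------------------------------------------------------------------
# protocol conveniences


def speed_protocol(cycle_duration_s: float, n_cycles: int = 30, **overrides) -> TrajectorySpec:
    """Constant-speed protocol with a given full-cycle duration.

    The cycle is split 45% seated plateau, 25% sit-to-stand transition, 5%
    standing plateau, 25% stand-to-sit transition; for the standard 24 / 14 /
    8 s protocols this yields transition phases of 6 / 3.5 / 2 s and active
    transition timings consistent with real recordings.
    """
    if cycle_duration_s <= 0:
        raise SpecError("cycle duration must be positive")
    return TrajectorySpec(
        n_cycles=n_cycles,
        sit_plateau_s=0.45 * cycle_duration_s,
        sit_to_stand_s=0.25 * cycle_duration_s,
        stand_plateau_s=0.05 * cycle_duration_s,
        stand_to_sit_s=0.25 * cycle_duration_s,
        cycle_duration_s=cycle_duration_s,
        **overrides,
    )


def mixed_speed_protocol(
    sequence_s: tuple[float, ...] = (1.0, 2.0, 4.0),
    n_repeats: int = 20,
    tempo_drift_frac: float = 0.08,
    **overrides,
) -> TrajectorySpec:
    """Repeating fast/normal/slow sequence (default 1 + 2 + 4 s, 7 s macro-period).

    The speed-variability condition is defined by irregular, unpaced
    execution, so the protocol carries a default 8% tempo drift across the
    recording; pass ``tempo_drift_frac=0`` for a metronomic sequence.
    """
    if n_repeats < 1:
        raise SpecError("n_repeats must be >= 1")
    return TrajectorySpec(
        n_cycles=len(sequence_s) * n_repeats,
        cycle_durations_s=tuple(sequence_s) * n_repeats,
        tempo_drift_frac=tempo_drift_frac,
        **overrides,
    )


def rocking_protocol(
    n_cycles: int = 10,
    rocking: RockingSpec = RockingSpec(),
    sit_to_stand_s: float = 1.9,
    stand_plateau_s: float = 0.4,
    stand_to_sit_s: float = 1.6,
    **overrides,
) -> TrajectorySpec:
    """Rocking condition: the whole seated plateau is occupied by rocking.

    The seated plateau equals the rocking span so the first seated peak
    coincides with settling into the seat, matching how preparatory rocking
    immediately precedes the rise.
    """
    return TrajectorySpec(
        n_cycles=n_cycles,
        sit_plateau_s=rocking.span_s,
        sit_to_stand_s=sit_to_stand_s,
        stand_plateau_s=stand_plateau_s,
        stand_to_sit_s=stand_to_sit_s,
        rocking=rocking,
        **overrides,
    )


# ---------------------------------------------------------------------------
# IF-cube synthesis


def synthesize_if_cube(
    trajectory_m: np.ndarray, scene: SceneSpec, config: RadarConfig
) -> IFCube:
    """Synthesize a raw IF cube from a torso range trajectory.

    Each slow-time snapshot t and channel c gets the fast-time signal

        sum_s A_s exp(j (2 pi f_b,s(t) k / f_s + 4 pi R_s(t) / lambda_c + phi_c))

    over the scatterers s (torso, optional hands, static clutter), with beat
    frequency f_b = 2 S R / c, plus white Gaussian noise whose power is
    ``snr_db`` below the torso echo power per fast-time sample. Real-mode
    sensors receive the real part. The trajectory is padded by holding its
    last value so the snapshot count fills whole frames. Deterministic for a
    fixed ``scene.rng_seed``.
    """
    trajectory_m = np.asarray(trajectory_m, dtype=float)
    if trajectory_m.ndim != 1 or trajectory_m.size == 0:
        raise SpecError("trajectory must be a non-empty 1-D array")
    derived = derive_radar_parameters(config)
    max_range = derived.max_range_m

    scatterer_tracks: list[tuple[np.ndarray, np.ndarray]] = []  # (range, amplitude) per snapshot

    m = config.chirps_per_frame
    n_frames = int(np.ceil(trajectory_m.size / m))
    pad = n_frames * m - trajectory_m.size
    traj = np.concatenate([trajectory_m, np.full(pad, trajectory_m[-1])])
    n_snap = traj.size

    if scene.torso_amplitude != 0.0:
        scatterer_tracks.append((traj, np.full(n_snap, float(scene.torso_amplitude))))
    if scene.hands is not None:
        hand_range = traj + scene.hands.range_offset_m
        midpoint = 0.5 * (traj.max() + traj.min())
        gate = (traj >= midpoint).astype(float)
        scatterer_tracks.append((hand_range, scene.hands.amplitude * gate))
    for rng_m, amp in scene.static_clutter:
        if not (0.0 <= rng_m < max_range):
            raise SpecError(f"clutter scatterer at {rng_m} m outside [0, {max_range:.3f}) m")
        scatterer_tracks.append((np.full(n_snap, float(rng_m)), np.full(n_snap, float(amp))))
    for ranges, _ in scatterer_tracks:
        if ranges.max(initial=0.0) >= max_range or ranges.min(initial=0.0) < 0.0:
            raise SpecError("scatterer trajectory leaves the unambiguous range interval")

    n = config.samples_per_chirp
    fs = config.adc_sample_rate_hz
    k = np.arange(n)
    base = np.zeros((n_snap, n), dtype=np.complex128)
    for ranges, amps in scatterer_tracks:
        f_beat = 2.0 * derived.chirp_slope_hz_per_s * ranges / 299_792_458.0
        phase = (2.0 * np.pi * f_beat / fs)[:, None] * k[None, :] + (
            4.0 * np.pi * ranges / derived.center_wavelength_m
        )[:, None]
        base += amps[:, None] * np.exp(1j * phase)

    offsets = scene.channel_phase_offsets_rad
    if offsets is None:
        offsets = (0.0,) * config.rx_channels
    if len(offsets) != config.rx_channels:
        raise SpecError(
            f"need {config.rx_channels} channel phase offsets, got {len(offsets)}"
        )

    rng = np.random.default_rng(scene.rng_seed)
    complex_mode = config.sampling_mode == "complex"
    dtype = np.complex64 if complex_mode else np.float32
    cube = np.empty((n_snap, config.rx_channels, n), dtype=dtype)
    sigma = 0.0
    if scene.snr_db is not None:
        # reference the torso echo; a zero-amplitude scene still gets unit-referenced noise
        ref = abs(scene.torso_amplitude) or 1.0
        sigma = ref * 10.0 ** (-scene.snr_db / 20.0)
    for c, phi in enumerate(offsets):
        channel = base * np.exp(1j * phi)
        if complex_mode:
            if sigma > 0.0:
                noise = rng.standard_normal((n_snap, n)) + 1j * rng.standard_normal((n_snap, n))
                channel = channel + sigma / np.sqrt(2.0) * noise
            cube[:, c, :] = channel.astype(np.complex64)
        else:
            real = channel.real
            if sigma > 0.0:
                real = real + sigma / np.sqrt(2.0) * rng.standard_normal((n_snap, n))
            cube[:, c, :] = real.astype(np.float32)

    samples = cube.reshape(n_frames, m, config.rx_channels, n).transpose(0, 2, 1, 3)
    return IFCube(samples=np.ascontiguousarray(samples), config=config)
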