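"""Seated-plateau edge and standing-valley detection.

Dual range thresholds split the smoothed trajectory into seated plateaus
(above ``theta_sit``) and standing valleys (below ``theta_stand``). For each
seated plateau the left edge marks the moment the subject fully settles into
the seat (first sample above ``theta_sit``) and the right edge the moment
they begin to rise (last sample above it); the standing valley is the range
minimum between two consecutive plateaus. A plateau that touches the first
or last sample of the recording has an undefined outer edge (the recording
started or ended mid-plateau); that edge is reported as NaN and cycles that
need it are skipped downstream.

Rocking trials fragment the seated period into several seated peaks between
two standing valleys; those are detected peak-wise instead of edge-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import NoCyclesError, ParameterError

DEFAULT_QUANTILE_MARGIN = 0.1
DEFAULT_MIN_PLATEAU_S = 0.25
DEFAULT_MIN_PEAK_SEPARATION_S = 0.4


@dataclass
class EventSet:
    """Seated-plateau edges and standing valleys, in seconds.

    ``left_edges_s`` and ``right_edges_s`` have one entry per detected
    seated plateau (NaN where the edge touches a recording boundary);
    ``valleys_s`` has one entry per gap between consecutive plateaus. The
    ordering invariant is left[i] <= right[i] < valley[i] < left[i+1].
    """

    theta_sit_m: float
    theta_stand_m: float
    left_edges_s: np.ndarray
    right_edges_s: np.ndarray
    valleys_s: np.ndarray
    valley_ranges_m: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.valleys_s)


@dataclass
class RockingEventSet:
    """Standing valleys and the seated peaks between consecutive valleys.

    ``valleys_s`` lists every detected standing valley;
    ``cycle_valley_bounds_s`` gives the (start valley, end valley) pair of
    each retained cycle and ``peak_times_s`` the ordered seated peaks inside
    it. Cycles without a seated peak are not retained.
    """

    theta_sit_m: float
    theta_stand_m: float
    valleys_s: np.ndarray
    cycle_valley_bounds_s: np.ndarray
    peak_times_s: list[np.ndarray]

    @property
    def n_cycles(self) -> int:
        return len(self.peak_times_s)


def select_thresholds(
    smoothed_m: np.ndarray,
    quantile_margin: float = DEFAULT_QUANTILE_MARGIN,
    min_span_m: float = 0.11,
) -> tuple[float, float]:
    """Place the seated/standing thresholds inside the trajectory span.

    Robust extrema (1st/99th percentiles) define the span; the seated
    threshold sits ``quantile_margin`` below the top and the standing
    threshold the same fraction above the bottom. A margin of 0.5 or more
    would collapse the two thresholds and is rejected, as is a track whose
    span is too small to contain sit-to-stand motion (default floor 0.11 m,
    about four range bins of the reference radar).
    """
    smoothed_m = np.asarray(smoothed_m, dtype=float)
    r_min, r_max = np.percentile(smoothed_m, [1.0, 99.0])
    span = r_max - r_min
    if span < min_span_m:
        raise NoCyclesError(
            f"trajectory span {span:.3f} m below {min_span_m:.3f} m; no sit-to-stand motion"
        )
    q = quantile_margin
    theta_sit = r_min + (1.0 - q) * span
    theta_stand = r_min + q * span
    if not theta_sit > theta_stand:
        raise ParameterError(
            f"quantile margin {q} collapses the thresholds (theta_sit <= theta_stand)"
        )
    return float(theta_sit), float(theta_stand)


def _seated_runs(above: np.ndarray, min_samples: int) -> list[tuple[int, int]]:
    """Contiguous True runs of at least ``min_samples``, as (start, end) inclusive."""
    padded = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_samples]


def detect_events(
    smoothed_m: np.ndarray,
    slow_time_step_s: float,
    theta_sit_m: float,
    theta_stand_m: float,
    min_plateau_s: float = DEFAULT_MIN_PLATEAU_S,
) -> EventSet:
    """Detect seated plateau edges and standing valleys.

    Each maximal excursion above ``theta_sit`` lasting at least
    ``min_plateau_s`` is one seated plateau (shorter excursions are threshold
    chatter and ignored); consecutive plateaus whose gap never drops below
    ``theta_stand`` are merged, so every reported gap contains exactly one
    standing valley.
    """
    if not theta_sit_m > theta_stand_m:
        raise ParameterError("theta_sit must exceed theta_stand")
    track = np.asarray(smoothed_m, dtype=float)
    min_samples = max(1, round(min_plateau_s / slow_time_step_s))
    runs = _seated_runs(track > theta_sit_m, min_samples)
    if not runs:
        raise NoCyclesError("trajectory never settles above theta_sit; no cycles detected")

    # merge plateau pairs without a standing dip between them
    merged: list[tuple[int, int]] = [runs[0]]
    for start, end in runs[1:]:
        prev_start, prev_end = merged[-1]
        gap = track[prev_end + 1 : start]
        if gap.size == 0 or gap.min() >= theta_stand_m:
            merged[-1] = (prev_start, end)
        else:
            merged.append((start, end))
    if len(merged) < 2:
        raise NoCyclesError("trajectory never descends below theta_stand; no cycles detected")

    last = track.size - 1
    left = np.array(
        [np.nan if (i == 0 and s == 0) else s * slow_time_step_s for i, (s, _) in enumerate(merged)]
    )
    right = np.array(
        [
            np.nan if (i == len(merged) - 1 and e == last) else e * slow_time_step_s
            for i, (_, e) in enumerate(merged)
        ]
    )
    valleys, valley_ranges = [], []
    for (s0, e0), (s1, _) in zip(merged[:-1], merged[1:]):
        gap = track[e0 + 1 : s1]
        k = int(np.argmin(gap))  # first occurrence on flat valleys
        valleys.append((e0 + 1 + k) * slow_time_step_s)
        valley_ranges.append(gap[k])
    return EventSet(
        theta_sit_m=theta_sit_m,
        theta_stand_m=theta_stand_m,
        left_edges_s=left,
        right_edges_s=right,
        valleys_s=np.asarray(valleys),
        valley_ranges_m=np.asarray(valley_ranges),
    )


def detect_rocking_events(
    smoothed_m: np.ndarray,
    slow_time_step_s: float,
    theta_sit_m: float,
    theta_stand_m: float,
    min_peak_separation_s: float = DEFAULT_MIN_PEAK_SEPARATION_S,
) -> RockingEventSet:
    """Detect standing valleys and the seated peaks between them.

    Valleys are the range minima of the maximal excursions below
    ``theta_stand``; between consecutive valleys, every local range maximum
    in the seated half of the span — above the midpoint of the two
    thresholds — is a seated peak. The gate sits below ``theta_sit`` because
    sub-second rocking oscillations are strongly attenuated by the
    trajectory smoother (roughly 0.28 gain at a 0.8 s period with the
    default window), which pulls the smoothed seated peaks under a threshold
    placed near the seated plateau level while leaving them far above the
    standing level. Peaks closer than ``min_peak_separation_s`` are merged
    (the higher one is kept). A cycle without any seated peak is dropped
    with a warning.
    """
    if not theta_sit_m > theta_stand_m:
        raise ParameterError("theta_sit must exceed theta_stand")
    track = np.asarray(smoothed_m, dtype=float)
    below_runs = _seated_runs(track < theta_stand_m, 1)
    if len(below_runs) < 2:
        raise NoCyclesError("fewer than two standing valleys; no rocking cycles detected")
    valleys_idx = np.array([s + int(np.argmin(track[s : e + 1])) for s, e in below_runs])

    distance = max(1, round(min_peak_separation_s / slow_time_step_s))
    seated_gate = 0.5 * (theta_sit_m + theta_stand_m)
    # reject numerical ripple on flat seated plateaus; real rocking dips are
    # far more prominent even after smoothing attenuation
    min_prominence = 0.05 * (theta_sit_m - theta_stand_m)
    bounds, peak_times = [], []
    for v0, v1 in zip(valleys_idx[:-1], valleys_idx[1:]):
        seg = track[v0 : v1 + 1]
        peaks, _ = find_peaks(seg, height=seated_gate, distance=distance, prominence=min_prominence)
        if peaks.size == 0:
            warnings.warn(f"no seated peak between valleys at {v0} and {v1}; cycle dropped")
            continue
        bounds.append((v0 * slow_time_step_s, v1 * slow_time_step_s))
        peak_times.append((v0 + peaks) * slow_time_step_s)
    if not peak_times:
        raise NoCyclesError("no cycle contains a seated peak above theta_sit")
    return RockingEventSet(
        theta_sit_m=theta_sit_m,
        theta_stand_m=theta_stand_m,
        valleys_s=valleys_idx.astype(float) * slow_time_step_s,
        cycle_valley_bounds_s=np.asarray(bounds, dtype=float),
        peak_times_s=peak_times,
    )
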