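"""Temporal, kinematic, spectral, and rocking features of sit-to-stand motion.

Conventions (cycle i runs from one seated left edge to the next):

* ``t_cycle`` — time between consecutive seated left-edge landmarks.
* ``t_descent`` — seated right edge (begin rise) to the standing valley,
  the range-*decreasing* phase.
* ``t_ascent`` — standing valley to the *next* seated left edge (settle),
  the range-*increasing* phase. Displacements follow the same windows, so
  ``d_ascent`` is positive and ``d_descent`` negative by construction.

The "ascent"/"descent" names follow the radial-range convention used in the
event framework; note that the body motion associated with increasing range
is sitting down, and with decreasing range standing up, for a subject-facing
radar watching the torso.

Per-cycle records are plain :class:`pandas.DataFrame` rows keyed by the gap
index between consecutive seated plateaus; entries whose defining landmark is
unavailable (recording started or ended mid-plateau) are NaN and skipped by
:func:`summarize`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoCyclesError, ParameterError
from .events import EventSet, RockingEventSet

DEFAULT_SEARCH_BAND_HZ = (0.01, 2.0)


# ---------------------------------------------------------------------------
# temporal


def temporal_features(events: EventSet) -> pd.DataFrame:
    """Per-cycle cycle/ascent/descent durations from detected landmarks.

    One row per gap between consecutive seated plateaus; ``t_cycle_s`` is
    NaN where either bounding left edge is undefined, and similarly for the
    phases.
    """
    le = events.left_edges_s
    re = events.right_edges_s
    tv = events.valleys_s
    if tv.size < 1 or le.size < 2:
        raise NoCyclesError("need at least two seated plateaus for temporal features")
    rows = []
    for i in range(tv.size):
        rows.append(
            {
                "cycle": i,
                "t_cycle_s": le[i + 1] - le[i],
                "t_descent_s": tv[i] - re[i],
                "t_ascent_s": le[i + 1] - tv[i],
            }
        )
    df = pd.DataFrame(rows)
    if df[["t_cycle_s", "t_descent_s", "t_ascent_s"]].isna().all().all():
        raise NoCyclesError("insufficient complete cycles (all landmarks at recording boundaries)")
    return df


# ---------------------------------------------------------------------------
# kinematic


def radial_velocity(smoothed_m: np.ndarray, slow_time_step_s: float) -> np.ndarray:
    """First temporal derivative of the range trajectory [m/s].

    Central differences in the interior, one-sided at the ends.
    """
    smoothed_m = np.asarray(smoothed_m, dtype=float)
    if smoothed_m.size < 3:
        raise ParameterError("need at least 3 samples to differentiate")
    return np.gradient(smoothed_m, slow_time_step_s)


def kinematic_features(
    smoothed_m: np.ndarray, slow_time_step_s: float, events: EventSet
) -> pd.DataFrame:
    """Per-cycle displacements, mean/peak velocities, and velocity ratio.

    Displacements are trajectory differences between the landmark samples
    (ascent: valley to next settle; descent: begin-rise to valley); mean
    velocities are displacement over phase duration; peak velocities are the
    extrema of the finite-difference velocity inside each closed phase
    window. The velocity ratio is the magnitude ratio of mean ascent to mean
    descent velocity.
    """
    track = np.asarray(smoothed_m, dtype=float)
    v = radial_velocity(track, slow_time_step_s)
    dt = slow_time_step_s

    def _idx(t: float) -> int:
        return int(round(t / dt))

    le, re, tv = events.left_edges_s, events.right_edges_s, events.valleys_s
    rows = []
    for i in range(tv.size):
        row = {
            "cycle": i,
            "d_ascent_m": np.nan,
            "d_descent_m": np.nan,
            "v_ascent_avg_mps": np.nan,
            "v_descent_avg_mps": np.nan,
            "v_ascent_peak_mps": np.nan,
            "v_descent_peak_mps": np.nan,
            "velocity_ratio": np.nan,
            "valid": True,
        }
        iv = _idx(tv[i])
        if np.isfinite(le[i + 1]):
            il = _idx(le[i + 1])
            t_asc = le[i + 1] - tv[i]
            if t_asc <= 0:
                row["valid"] = False
            else:
                row["d_ascent_m"] = track[il] - track[iv]
                row["v_ascent_avg_mps"] = row["d_ascent_m"] / t_asc
                row["v_ascent_peak_mps"] = float(np.max(v[iv : il + 1]))
        if np.isfinite(re[i]):
            ir = _idx(re[i])
            t_desc = tv[i] - re[i]
            if t_desc <= 0:
                row["valid"] = False
            else:
                row["d_descent_m"] = track[iv] - track[ir]
                row["v_descent_avg_mps"] = row["d_descent_m"] / t_desc
                row["v_descent_peak_mps"] = float(np.min(v[ir : iv + 1]))
        if np.isfinite(row["v_ascent_avg_mps"]) and np.isfinite(row["v_descent_avg_mps"]):
            row["velocity_ratio"] = abs(row["v_ascent_avg_mps"]) / abs(row["v_descent_avg_mps"])
        rows.append(row)
    return pd.DataFrame(rows)


def cycle_features(
    smoothed_m: np.ndarray, slow_time_step_s: float, events: EventSet
) -> pd.DataFrame:
    """Temporal and kinematic per-cycle features merged on the cycle index."""
    t = temporal_features(events)
    k = kinematic_features(smoothed_m, slow_time_step_s, events)
    return t.merge(k, on="cycle")


# ---------------------------------------------------------------------------
# spectral


@dataclass(frozen=True)
class SpectralFeatures:
    """Dominant cadence frequency and half-power bandwidth of the trajectory."""

    f_peak_hz: float
    cycle_period_s: float
    bw_3db_hz: float
    f_lo_hz: float
    f_hi_hz: float
    frequency_resolution_hz: float
    search_band_hz: tuple[float, float]
    lo_at_band_edge: bool = False
    hi_at_band_edge: bool = False


def spectral_features(
    smoothed_m: np.ndarray,
    slow_time_step_s: float,
    search_band_hz: tuple[float, float] = DEFAULT_SEARCH_BAND_HZ,
    pad_factor: int = 4,
) -> SpectralFeatures:
    """Dominant cycle frequency and -3 dB bandwidth of the range trajectory.

    The mean is removed (the raw trajectory is DC-dominated), the magnitude
    spectrum is evaluated on a grid zero-padded to at least ``pad_factor``
    times the signal length (rounded up to a power of two), and the peak is
    the argmax within the search band. The half-power bounds are found by
    linear interpolation where the magnitude first drops below peak/sqrt(2)
    on each side of the peak; a side that never drops within the band is
    clamped to the band edge and flagged.
    """
    track = np.asarray(smoothed_m, dtype=float)
    if track.size < 8:
        raise ParameterError("trajectory too short for spectral analysis")
    lo, hi = search_band_hz
    if not (0.0 <= lo < hi):
        raise ParameterError("invalid spectral search band")
    if pad_factor < 1:
        raise ParameterError("pad_factor must be >= 1")
    x = track - track.mean()
    n_fft = 1 << int(np.ceil(np.log2(pad_factor * track.size)))
    mag = np.abs(np.fft.rfft(x, n_fft))
    freq = np.fft.rfftfreq(n_fft, slow_time_step_s)
    df = freq[1] - freq[0]

    band = (freq >= lo) & (freq <= hi)
    if not band.any():
        raise ParameterError("spectral search band is empty on this frequency grid")
    b0 = int(np.flatnonzero(band)[0])
    b1 = int(np.flatnonzero(band)[-1])
    peak_idx = b0 + int(np.argmax(mag[b0 : b1 + 1]))
    peak = mag[peak_idx]
    target = peak / np.sqrt(2.0)

    def _cross(direction: int, stop: int) -> tuple[float, bool]:
        i = peak_idx
        while i != stop and mag[i] >= target:
            i += direction
        if mag[i] >= target:  # never dropped inside the band
            return freq[stop], True
        prev = i - direction
        f = np.interp(target, [mag[i], mag[prev]], [freq[i], freq[prev]])
        return float(f), False

    f_lo, lo_edge = _cross(-1, b0)
    f_hi, hi_edge = _cross(+1, b1)
    return SpectralFeatures(
        f_peak_hz=float(freq[peak_idx]),
        cycle_period_s=float(1.0 / freq[peak_idx]),
        bw_3db_hz=float(f_hi - f_lo),
        f_lo_hz=f_lo,
        f_hi_hz=f_hi,
        frequency_resolution_hz=float(df),
        search_band_hz=(lo, hi),
        lo_at_band_edge=lo_edge,
        hi_at_band_edge=hi_edge,
    )


# ---------------------------------------------------------------------------
# rocking


def rocking_features(rocking: RockingEventSet) -> pd.DataFrame:
    """Per-cycle temporal decomposition of rocking transitions.

    For each cycle bounded by standing valleys (t_v, t_v'), with seated peaks
    t_p(1)..t_p(k) between them: cycle duration t_v' - t_v; descent
    t_p(1) - t_v; rocking span t_p(k) - t_p(1); final ascent t_v' - t_p(k);
    standing transition t_v' - t_p(1). The identity
    ``t_stand = t_rock + t_ascent`` holds exactly by construction.
    """
    if rocking.n_cycles < 1:
        raise NoCyclesError("no rocking cycles available")
    rows = []
    for i, peaks in enumerate(rocking.peak_times_s):
        v0, v1 = rocking.cycle_valley_bounds_s[i]
        first, last = peaks[0], peaks[-1]
        rows.append(
            {
                "cycle": i,
                "n_seated_peaks": len(peaks),
                "t_cycle_s": v1 - v0,
                "t_descent_s": first - v0,
                "t_rock_s": last - first,
                "t_ascent_s": v1 - last,
                "t_stand_s": v1 - first,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries


def summarize(per_cycle: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """Mean and sample standard deviation (n-1) of each feature over cycles.

    NaN entries (cycles whose landmark fell on a recording boundary) and
    cycles flagged invalid are excluded per feature; a feature observed in a
    single cycle reports a standard deviation of 0 with ``n = 1``.
    """
    df = per_cycle.copy()
    if "valid" in df.columns:
        df = df[df["valid"].fillna(True)]
        df = df.drop(columns=["valid"])
    feature_cols = [c for c in df.columns if c not in ("cycle", "n_seated_peaks")]
    rows = []
    for col in feature_cols:
        values = df[col].dropna()
        if values.empty:
            continue
        n = int(values.size)
        rows.append(
            {
                "feature": col,
                "mean": float(values.mean()),
                "std": 0.0 if n == 1 else float(values.std(ddof=1)),
                "n_cycles": n,
            }
        )
    if not rows:
        raise NoCyclesError("no valid cycles to summarize")
    out = pd.DataFrame(rows)
    if condition is not None:
        out.insert(0, "condition", condition)
    return out
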