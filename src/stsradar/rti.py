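"""Range-time intensity (RTI) processing: IF cube to calibrated dB map.

The processing chain is: average the receive channels, unroll (frame, chirp)
into one uniform slow-time axis, apply a Blackman-windowed range FFT along
fast time, optionally remove static clutter by complex mean subtraction, and
convert to log power. The result is a matrix RTI(t, r) whose ridges trace the
radial motion of reflectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import blackman

from .config import DerivedParams, RadarConfig, derive_radar_parameters, retained_bin_count
from .errors import ParameterError

#: Floor added inside the log so that empty bins map to a finite dB value.
LOG_EPSILON = 1e-12


@dataclass
class IFCube:
    """Raw intermediate-frequency samples x(n, c, m, k).

    Axes: frame n, receive channel c, chirp m, fast-time sample k. The array
    is complex for complex-baseband sensors and real otherwise; the attached
    :class:`RadarConfig` fixes the expected shape.
    """

    samples: np.ndarray
    config: RadarConfig

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.ndim != 4:
            raise ParameterError(f"IF cube must be 4-D (frame, channel, chirp, sample), got {s.ndim}-D")
        if s.size == 0:
            raise ParameterError("IF cube is empty")
        expected = (self.config.rx_channels, self.config.chirps_per_frame, self.config.samples_per_chirp)
        if s.shape[1:] != expected:
            raise ParameterError(
                f"IF cube trailing axes {s.shape[1:]} do not match config (C, M, N) = {expected}"
            )
        self.samples = s

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.n_frames * self.config.chirps_per_frame


@dataclass
class RTIMap:
    """dB-scaled slow-time x range matrix with physical axes."""

    intensity_db: np.ndarray
    time_axis_s: np.ndarray
    range_axis_m: np.ndarray
    config: RadarConfig
    derived: DerivedParams
    clutter_filtered: bool = False


def average_channels(cube: IFCube) -> np.ndarray:
    """Arithmetic mean over the receive-channel axis -> x̄(n, m, k).

    Averaging C channels with i.i.d. noise lowers the noise variance by 1/C
    while leaving a common signal untouched.
    """
    return cube.samples.mean(axis=1)


def to_slow_time(averaged: np.ndarray, config: RadarConfig) -> tuple[np.ndarray, np.ndarray]:
    """Unroll (frame, chirp) into one linear slow-time axis.

    Row ``t = n * M + m`` holds chirp m of frame n; the physical time of row t
    is ``t * T_frame / M``, i.e. chirps are treated as uniformly spaced within
    the frame.

    Returns (matrix of shape (n_frames * M, N), time axis in seconds).
    """
    averaged = np.asarray(averaged)
    expected = (config.chirps_per_frame, config.samples_per_chirp)
    if averaged.ndim != 3 or averaged.shape[1:] != expected:
        raise ParameterError(
            f"expected array of shape (n_frames, {expected[0]}, {expected[1]}), got {averaged.shape}"
        )
    n_rows = averaged.shape[0] * config.chirps_per_frame
    matrix = averaged.reshape(n_rows, config.samples_per_chirp)
    step = config.frame_repetition_time_s / config.chirps_per_frame
    return matrix, np.arange(n_rows) * step


def range_fft(matrix: np.ndarray, config: RadarConfig, n_fft: int | None = None) -> np.ndarray:
    """Blackman-windowed FFT along fast time, one-sided spectrum retained.

    For complex baseband all ``n_fft`` bins correspond to positive beat
    frequencies and are kept; for real baseband only the first
    ``n_fft // 2 + 1`` bins are kept.
    """
    matrix = np.asarray(matrix)
    n = config.samples_per_chirp
    if matrix.shape[-1] != n:
        raise ParameterError(f"fast-time axis has {matrix.shape[-1]} samples, expected {n}")
    n_fft = n if n_fft is None else int(n_fft)
    retained = retained_bin_count(config, n_fft)  # also validates n_fft >= N
    window = blackman(n, sym=False)
    spectrum = np.fft.fft(matrix * window, n=n_fft, axis=-1)
    return spectrum[..., :retained]


def remove_static_clutter(profiles: np.ndarray) -> np.ndarray:
    """Zero-Doppler removal: subtract the slow-time complex mean per range bin.

    Operates on the complex range profiles (linear domain, before the log).
    Static reflectors contribute a constant phasor per bin and are cancelled;
    moving reflectors sweep through bins and survive. With a single snapshot
    the mean equals the data and nothing sensible can be subtracted, so the
    input is returned unchanged with a warning.
    """
    profiles = np.asarray(profiles)
    if profiles.shape[0] < 2:
        warnings.warn("clutter filter needs >= 2 slow-time snapshots; returning input unchanged")
        return profiles
    return profiles - profiles.mean(axis=0, keepdims=True)


def mti_filter(profiles: np.ndarray, window: int = 2) -> np.ndarray:
    """Two-pulse / moving-average MTI alternative to mean subtraction.

    Subtracts a causal moving average of the previous ``window`` snapshots
    from each snapshot (first ``window`` rows use the available history).
    """
    profiles = np.asarray(profiles)
    if window < 1:
        raise ParameterError("MTI window must be >= 1")
    if profiles.shape[0] < 2:
        warnings.warn("MTI filter needs >= 2 slow-time snapshots; returning input unchanged")
        return profiles
    out = np.empty_like(profiles)
    csum = np.cumsum(profiles, axis=0)
    for t in range(profiles.shape[0]):
        lo = max(0, t - window)
        if t == 0:
            out[t] = profiles[t] - profiles[t]
        else:
            avg = (csum[t - 1] - (csum[lo - 1] if lo > 0 else 0)) / (t - lo)
            out[t] = profiles[t] - avg
    return out


def compute_rti(
    profiles: np.ndarray,
    config: RadarConfig,
    *,
    n_fft: int | None = None,
    time_axis_s: np.ndarray | None = None,
    clutter_filtered: bool = False,
) -> RTIMap:
    """Convert complex range profiles to a dB-scaled RTI map with axes.

    RTI(t, r) = 10 log10(|X(t, r)|^2 + eps); the range axis comes from the
    beat-frequency-to-range mapping of the FFT bin grid.
    """
    profiles = np.asarray(profiles)
    derived = derive_radar_parameters(config, n_fft=n_fft)
    if profiles.shape[-1] != derived.retained_bins:
        raise ParameterError(
            f"profiles have {profiles.shape[-1]} range bins, expected {derived.retained_bins}"
        )
    if time_axis_s is None:
        time_axis_s = np.arange(profiles.shape[0]) * derived.slow_time_step_s
    intensity = 10.0 * np.log10(np.abs(profiles) ** 2 + LOG_EPSILON)
    return RTIMap(
        intensity_db=intensity,
        time_axis_s=np.asarray(time_axis_s),
        range_axis_m=derived.range_axis(),
        config=config,
        derived=derived,
        clutter_filtered=clutter_filtered,
    )


def rti_from_cube(
    cube: IFCube,
    *,
    remove_clutter: bool = False,
    clutter_method: str = "mean",
    n_fft: int | None = None,
) -> RTIMap:
    """Full chain: channel average -> slow-time unroll -> range FFT -> dB map."""
    averaged = average_channels(cube)
    matrix, time_axis = to_slow_time(averaged, cube.config)
    profiles = range_fft(matrix, cube.config, n_fft=n_fft)
    if remove_clutter:
        if clutter_method == "mean":
            profiles = remove_static_clutter(profiles)
        elif clutter_method == "mti":
            profiles = mti_filter(profiles)
        else:
            raise ParameterError(f"unknown clutter method {clutter_method!r}")
    return compute_rti(
        profiles,
        cube.config,
        n_fft=n_fft,
        time_axis_s=time_axis,
        clutter_filtered=remove_clutter,
    )
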