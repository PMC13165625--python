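"""Radar acquisition parameters and derived physical quantities.

The acquisition is a 60 GHz FMCW sweep: a chirp of bandwidth ``B`` sampled at
``adc_sample_rate`` for ``samples_per_chirp`` fast-time samples, repeated
``chirps_per_frame`` times per frame on ``rx_channels`` receive antennas.
Everything downstream (range axis, slow-time axis, velocity limits) is a pure
function of these numbers, collected here in :class:`DerivedParams` so that no
other module re-derives radar physics.

Two distinct chirp intervals coexist and are never interchanged:

* the hardware chirp repetition interval (sets the unambiguous velocity), and
* the uniform slow-time step ``frame_repetition_time / chirps_per_frame``
  used for the time axis of the range-time map.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError

#: Speed of light in vacuum [m/s].
C_LIGHT = 299_792_458.0

_SAMPLING_MODES = ("real", "complex")


@dataclass(frozen=True)
class RadarConfig:
    """FMCW acquisition parameters (SI units).

    The defaults reproduce the reference 60 GHz sensor configuration used
    throughout the package: 58-63.5 GHz sweep (5.5 GHz bandwidth), 64 ADC
    samples per chirp at 2 MHz, 64 chirps per 77.27 ms frame, 3 RX channels.
    """

    f_start_hz: float = 58.0e9
    f_end_hz: float = 63.5e9
    chirp_repetition_time_s: float = 0.591e-3
    frame_repetition_time_s: float = 77.27e-3
    adc_sample_rate_hz: float = 2.0e6
    samples_per_chirp: int = 64
    chirps_per_frame: int = 64
    rx_channels: int = 3
    if_gain_db: float = 23.0
    sampling_mode: str = "complex"

    def __post_init__(self) -> None:
        if self.bandwidth_hz <= 0:
            raise ConfigurationError(
                f"bandwidth must be positive, got f_start={self.f_start_hz} Hz "
                f">= f_end={self.f_end_hz} Hz"
            )
        for name in ("samples_per_chirp", "chirps_per_frame", "rx_channels"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        for name in (
            "chirp_repetition_time_s",
            "frame_repetition_time_s",
            "adc_sample_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.frame_repetition_time_s < self.chirps_per_frame * self.chirp_repetition_time_s:
            raise ConfigurationError(
                "chirp burst does not fit in the frame: frame_repetition_time_s "
                f"{self.frame_repetition_time_s} < chirps_per_frame * chirp_repetition_time_s "
                f"{self.chirps_per_frame * self.chirp_repetition_time_s}"
            )
        if self.sampling_mode not in _SAMPLING_MODES:
            raise ConfigurationError(
                f"sampling_mode must be one of {_SAMPLING_MODES}, got {self.sampling_mode!r}"
            )

    @property
    def bandwidth_hz(self) -> float:
        """Sweep bandwidth B = f_end - f_start [Hz]."""
        return self.f_end_hz - self.f_start_hz

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RadarConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown radar configuration fields: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RadarConfig":
        return cls.from_dict(json.loads(text))

    def sha256(self) -> str:
        """Stable content hash used to bind data containers to their config."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass(frozen=True)
class DerivedParams:
    """Quantities derived from a :class:`RadarConfig` (SI units)."""

    t_adc_s: float
    chirp_slope_hz_per_s: float
    range_bin_spacing_m: float
    retained_bins: int
    max_range_m: float
    center_wavelength_m: float
    max_velocity_mps: float
    slow_time_step_s: float
    frame_rate_hz: float

    def range_axis(self) -> np.ndarray:
        """Physical range of each retained FFT bin [m], starting at 0."""
        return np.arange(self.retained_bins) * self.range_bin_spacing_m

    def beat_frequency_to_range(self, f_beat_hz: np.ndarray | float) -> np.ndarray | float:
        """Convert a beat frequency to range, R = c * f_b / (2 S)."""
        return C_LIGHT * np.asarray(f_beat_hz) / (2.0 * self.chirp_slope_hz_per_s)


def retained_bin_count(config: RadarConfig, n_fft: int | None = None) -> int:
    """Number of one-sided range bins retained after the range FFT.

    Complex baseband keeps all ``n_fft`` bins (every beat frequency is
    positive for an approaching-range geometry); real baseband keeps the
    one-sided half ``n_fft // 2 + 1``.
    """
    n_fft = config.samples_per_chirp if n_fft is None else int(n_fft)
    if n_fft < config.samples_per_chirp:
        raise ParameterError(
            f"n_fft ({n_fft}) must be >= samples_per_chirp ({config.samples_per_chirp})"
        )
    if config.sampling_mode == "complex":
        return n_fft
    return n_fft // 2 + 1


def derive_radar_parameters(config: RadarConfig, n_fft: int | None = None) -> DerivedParams:
    """Compute all derived physical quantities for a radar configuration.

    With the default FFT length (no zero padding) the range-bin spacing is
    the classic FMCW resolution c / (2B); zero padding refines the grid
    without changing the underlying resolution.
    """
    n_fft = config.samples_per_chirp if n_fft is None else int(n_fft)
    t_adc = config.samples_per_chirp / config.adc_sample_rate_hz
    slope = config.bandwidth_hz / t_adc
    # beat-frequency bin width is fs / n_fft; R = c f_b / (2S) maps it to range
    delta_r = C_LIGHT * (config.adc_sample_rate_hz / n_fft) / (2.0 * slope)
    retained = retained_bin_count(config, n_fft)
    f_center = 0.5 * (config.f_start_hz + config.f_end_hz)
    wavelength = C_LIGHT / f_center
    return DerivedParams(
        t_adc_s=t_adc,
        chirp_slope_hz_per_s=slope,
        range_bin_spacing_m=delta_r,
        retained_bins=retained,
        max_range_m=retained * delta_r,
        center_wavelength_m=wavelength,
        max_velocity_mps=wavelength / (4.0 * config.chirp_repetition_time_s),
        slow_time_step_s=config.frame_repetition_time_s / config.chirps_per_frame,
        frame_rate_hz=1.0 / config.frame_repetition_time_s,
    )


def default_config() -> RadarConfig:
    """The bundled reference configuration (see :class:`RadarConfig` defaults)."""
    return RadarConfig()
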