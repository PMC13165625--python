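"""On-disk containers and the end-to-end pipeline driver.

IF cubes are stored as a flat little-endian binary of 32-bit floats in
(frame, channel, chirp, sample) order — complex data interleaves real and
imaginary parts in a trailing axis of length 2 — next to a JSON sidecar
carrying the array shape, dtype, the full radar configuration and its
content hash, and provenance (seed, creation time). The format is trivially
portable and needs no heavy dependency.
"""

from __future__ import annotations

import datetime
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RadarConfig
from .errors import FormatError
from .events import (
    DEFAULT_QUANTILE_MARGIN,
    EventSet,
    RockingEventSet,
    detect_events,
    detect_rocking_events,
    select_thresholds,
)
from .features import (
    SpectralFeatures,
    cycle_features,
    rocking_features,
    spectral_features,
    summarize,
)
from .rti import IFCube, RTIMap, rti_from_cube
from .trajectory import DEFAULT_POLY_ORDER, DEFAULT_WINDOW, RangeTrack, extract_track

logger = logging.getLogger("stsradar")

_SIDECAR_SUFFIX = ".json"
_BINARY_SUFFIX = ".bin"


def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (_BINARY_SUFFIX, _SIDECAR_SUFFIX):
        base = base.with_suffix("")
    return base.with_suffix(_BINARY_SUFFIX), base.with_suffix(_SIDECAR_SUFFIX)


def write_if_cube(path: str | Path, cube: IFCube, seed: int | None = None) -> Path:
    """Write an IF cube and its JSON sidecar; returns the binary path."""
    bin_path, sidecar_path = _paths(path)
    samples = cube.samples
    complex_mode = np.iscomplexobj(samples)
    if complex_mode:
        flat = np.stack([samples.real, samples.imag], axis=-1).astype("<f4")
    else:
        flat = samples.astype("<f4")
    flat.tofile(bin_path)
    sidecar = {
        "shape": list(samples.shape),
        "complex": complex_mode,
        "dtype": "<f4",
        "order": "frame,channel,chirp,sample" + (",re/im" if complex_mode else ""),
        "config": cube.config.to_dict(),
        "config_sha256": cube.config.sha256(),
        "seed": seed,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return bin_path


def read_if_cube(path: str | Path) -> IFCube:
    """Read an IF cube written by :func:`write_if_cube`.

    Raises :class:`FormatError` when the sidecar is missing, the binary size
    does not match the declared shape, or the stored configuration hash
    disagrees with the configuration itself.
    """
    bin_path, sidecar_path = _paths(path)
    if not sidecar_path.exists():
        raise FormatError(f"sidecar {sidecar_path} not found next to {bin_path}")
    if not bin_path.exists():
        raise FormatError(f"cube binary {bin_path} not found")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        shape = tuple(int(s) for s in sidecar["shape"])
        complex_mode = bool(sidecar["complex"])
        config = RadarConfig.from_dict(sidecar["config"])
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    if sidecar.get("config_sha256") != config.sha256():
        raise FormatError(f"config hash mismatch in {sidecar_path}")
    expected = int(np.prod(shape)) * (2 if complex_mode else 1)
    data = np.fromfile(bin_path, dtype="<f4")
    if data.size != expected:
        raise FormatError(
            f"cube binary {bin_path} holds {data.size} float32 values, expected {expected} "
            f"for shape {shape}{' complex' if complex_mode else ''}"
        )
    if complex_mode:
        data = data.reshape(*shape, 2)
        samples = (data[..., 0] + 1j * data[..., 1]).astype(np.complex64)
    else:
        samples = data.reshape(shape)
    return IFCube(samples=samples, config=config)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    """Everything the cube-to-features pipeline produces."""

    rti: RTIMap
    track: RangeTrack
    events: EventSet | RockingEventSet
    per_cycle: pd.DataFrame
    spectral: SpectralFeatures
    summary: pd.DataFrame


def run_pipeline(
    cube: IFCube,
    *,
    remove_clutter: bool = True,
    rocking: bool = False,
    frame_level: bool = False,
    quantile_margin: float = DEFAULT_QUANTILE_MARGIN,
    search_band_m: tuple[float, float] | None = None,
    window_samples: int = DEFAULT_WINDOW,
    poly_order: int = DEFAULT_POLY_ORDER,
    condition: str | None = None,
) -> PipelineResult:
    """Run RTI formation, tracking, event detection, and feature extraction.

    With ``rocking=True`` the peak-based rocking event detector and features
    replace the edge-based ones. Deterministic given its inputs.
    """
    t0 = time.perf_counter()
    rti = rti_from_cube(cube, remove_clutter=remove_clutter)
    logger.info("RTI map: %d snapshots x %d bins (%.2f s)", *rti.intensity_db.shape, time.perf_counter() - t0)

    track = extract_track(
        rti,
        search_band_m=search_band_m,
        window_samples=window_samples,
        poly_order=poly_order,
        frame_level=frame_level,
    )
    theta_sit, theta_stand = select_thresholds(track.smoothed_m, quantile_margin)
    logger.info("thresholds: theta_sit=%.3f m theta_stand=%.3f m", theta_sit, theta_stand)

    if rocking:
        ev = detect_rocking_events(track.smoothed_m, track.slow_time_step_s, theta_sit, theta_stand)
        per_cycle = rocking_features(ev)
    else:
        ev = detect_events(track.smoothed_m, track.slow_time_step_s, theta_sit, theta_stand)
        per_cycle = cycle_features(track.smoothed_m, track.slow_time_step_s, ev)
    logger.info("detected %d cycles", ev.n_cycles)

    spectral = spectral_features(track.smoothed_m, track.slow_time_step_s)
    summary = summarize(per_cycle, condition=condition)
    return PipelineResult(
        rti=rti, track=track, events=ev, per_cycle=per_cycle, spectral=spectral, summary=summary
    )


# ---------------------------------------------------------------------------
# CSV/JSON exports


def write_track_csv(path: str | Path, track: RangeTrack) -> None:
    pd.DataFrame(
        {
            "time_s": track.time_axis_s,
            "raw_range_m": track.raw_m,
            "smoothed_range_m": track.smoothed_m,
        }
    ).to_csv(path, index=False)


def read_track_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a track CSV; returns (time axis, smoothed range, slow-time step)."""
    df = pd.read_csv(path)
    for col in ("time_s", "smoothed_range_m"):
        if col not in df.columns:
            raise FormatError(f"track CSV {path} lacks required column {col!r}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise FormatError(f"track CSV {path} too short")
    return t, df["smoothed_range_m"].to_numpy(), float(t[1] - t[0])


def write_events_csv(path: str | Path, events: EventSet) -> None:
    n = events.valleys_s.size
    pd.DataFrame(
        {
            "cycle_index": np.arange(n),
            "t_settle_s": events.left_edges_s[:n],
            "t_begin_rise_s": events.right_edges_s[:n],
            "t_standing_s": events.valleys_s,
        }
    ).to_csv(path, index=False)


def write_events_json(path: str | Path, events: EventSet) -> None:
    payload = {
        "theta_sit_m": events.theta_sit_m,
        "theta_stand_m": events.theta_stand_m,
        "left_edges_s": [None if np.isnan(v) else v for v in events.left_edges_s],
        "right_edges_s": [None if np.isnan(v) else v for v in events.right_edges_s],
        "valleys_s": list(events.valleys_s),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
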