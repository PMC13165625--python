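import numpy as np
import pytest

import stsradar as sr


@pytest.fixture(scope="session")
def config() -> sr.RadarConfig:
    return sr.default_config()


@pytest.fixture(scope="session")
def derived(config) -> sr.DerivedParams:
    return sr.derive_radar_parameters(config)


@pytest.fixture(scope="session")
def dt(derived) -> float:
    return derived.slow_time_step_s


@pytest.fixture(scope="session")
def fast_recording(dt):
    """Noiseless 30-cycle fast-protocol trajectory with ground truth."""
    spec = sr.speed_protocol(8.0, n_cycles=30)
    return sr.build_sts_trajectory(spec, dt)


@pytest.fixture(scope="session")
def fast_track(fast_recording):
    """Savitzky-Golay smoothed version of the fast-protocol trajectory."""
    trajectory, _ = fast_recording
    return sr.smooth_trajectory(trajectory)


def naive_dft(matrix: np.ndarray, window: np.ndarray, retained: int) -> np.ndarray:
    """Brute-force O(N^2) windowed DFT oracle, independent of numpy.fft."""
    matrix = np.asarray(matrix) * window
    n = matrix.shape[-1]
    k = np.arange(n)
    out = np.empty(matrix.shape[:-1] + (retained,), dtype=complex)
    for r in range(retained):
        out[..., r] = (matrix * np.exp(-2j * np.pi * r * k / n)).sum(axis=-1)
    return out
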