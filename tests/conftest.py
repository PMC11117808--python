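import numpy as np
import pytest

from sspdim import (
    AnalysisWindows,
    ContinuousRecording,
    EpochedRecording,
    cap_sensor_array,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sensors():
    return cap_sensor_array(n=31)


@pytest.fixture
def sim_windows():
    """Analysis windows of the simulated study: signal 0-500 ms at 9-11 Hz,
    baseline -200-0 ms."""
    return AnalysisWindows(
        signal_tmin=0.0, signal_tmax=0.5,
        baseline_tmin=-0.2, baseline_tmax=0.0,
        fmin=9.0, fmax=11.0,
    )


def make_continuous(data, srate=1000.0):
    data = np.asarray(data, dtype=float)
    ids = [f"ch{i:02d}" for i in range(data.shape[0])]
    return ContinuousRecording(data=data, srate=srate, channel_ids=ids)


def make_epochs(data, srate=1000.0, tmin=-0.2):
    """Epochs from a (channels, trials, times) array with t=0 on-grid."""
    data = np.asarray(data, dtype=float)
    n0 = int(round(tmin * srate))
    times = np.arange(n0, n0 + data.shape[2]) / srate
    ids = [f"ch{i:02d}" for i in range(data.shape[0])]
    return EpochedRecording(data=data, srate=srate, times=times, channel_ids=ids)


@pytest.fixture
def tiny_epochs(rng):
    """4 channels x 6 trials x 1 s of band-limited noise plus a 10 Hz burst."""
    from scipy import signal as sp

    srate = 1000.0
    n_t = 1001
    times = np.arange(-200, 801) / srate
    sos = sp.butter(4, [1, 40], btype="bandpass", fs=srate, output="sos")
    noise = sp.sosfiltfilt(sos, rng.standard_normal((4, 6, n_t)), axis=2)
    burst = np.where((times >= 0) & (times < 0.5), np.sin(2 * np.pi * 10 * times), 0.0)
    pattern = np.array([1.0, 0.5, -0.75, 0.25])
    data = 20 * noise + 100 * pattern[:, None, None] * burst[None, None, :]
    return make_epochs(data, srate=srate)
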