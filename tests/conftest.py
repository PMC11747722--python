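import numpy as np
import pytest

from lungbrain import SynthConfig, WaveformRecording


@pytest.fixture(scope="session")
def fast_cfg() -> SynthConfig:
    """Small but structurally complete study configuration."""
    return SynthConfig(sampling_rate=32.0, period_minutes=6.0,
                       washout_minutes=6.0, n_animals=4, seed=7)


def make_recording(channels: dict, fs: float = 32.0) -> WaveformRecording:
    return WaveformRecording(
        channels={k: np.asarray(v, dtype=float) for k, v in channels.items()},
        sampling_rate=fs)


@pytest.fixture
def sinusoid_icp_rec() -> WaveformRecording:
    """60 s of ICP = 10 + 2*sin(cardiac) plus a constant ABP pulse, 32 Hz."""
    fs, f_c = 32.0, 1.6
    t = np.arange(int(60 * fs)) / fs
    icp = 10.0 + 2.0 * np.sin(2 * np.pi * f_c * t)
    abp = 85.0 + 15.0 * np.sin(2 * np.pi * f_c * t)
    return make_recording({"ICP": icp, "ABP": abp}, fs=fs)
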