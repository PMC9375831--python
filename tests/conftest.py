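import numpy as np
import pytest

from pulsebench import SampledSignal, SynthConfig, synth_ppg


@pytest.fixture(scope="session")
def clean_ppg_72():
    """Clean synthetic PPG at ~72 bpm, 120 s at 64 Hz, with ground truth."""
    cfg = SynthConfig(hr_bpm=72.0, sdnn_ms=30.0, duration_s=120.0, seed=11)
    sig, peaks, rr = synth_ppg(cfg)
    return cfg, sig, peaks, rr


@pytest.fixture()
def sine_signal():
    """1.2 Hz sinusoid, 30 s at 30.30 Hz."""
    fs = 30.30
    t = np.arange(int(30 * fs)) / fs
    return SampledSignal(np.sin(2 * np.pi * 1.2 * t), fs, label="sine")


def dominant_frequency(values: np.ndarray, fs: float) -> float:
    """FFT oracle: frequency of the largest windowed-spectrum magnitude."""
    x = np.asarray(values, float)
    x = (x - x.mean()) * np.hanning(x.size)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    mag = np.abs(np.fft.rfft(x))
    return float(freqs[np.argmax(mag)])


def band_energy(values: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """FFT oracle: total spectral energy inside [lo, hi] Hz."""
    x = np.asarray(values, float)
    x = x - x.mean()
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    power = np.abs(np.fft.rfft(x)) ** 2
    sel = (freqs >= lo) & (freqs <= hi)
    return float(power[sel].sum())
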