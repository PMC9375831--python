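"""Signal containers, resampling, and the fixed contact-BVP filtering chain.

A contact blood-volume-pulse (BVP) recording — e.g. from a wrist-worn optical
sensor sampled at 64 Hz — is brought onto the working rate of the remote
pipeline and cleaned with a fixed chain: band-limited resampling, a
Savitzky-Golay smoother, and a zero-phase Butterworth band-pass restricted to
the plausible pulse band (0.7–7 Hz, i.e. 42–420 bpm with harmonics).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .errors import InvalidArgument, TooShortSignal

__all__ = [
    "SampledSignal",
    "FilterConfig",
    "resample",
    "savgol_smooth",
    "butter_bandpass",
    "preprocess_bvp",
]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled 1-D waveform.

    Parameters
    ----------
    values : array-like
        Sample values, arbitrary units. Must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text tag, e.g. ``"BVP"`` or ``"rPPG"``.
    """

    values: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise InvalidArgument("signal must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)):
            raise InvalidArgument("signal values must be finite")
        if not (self.fs > 0):
            raise InvalidArgument(f"sampling rate must be > 0, got {self.fs}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Duration in seconds (n samples at fs)."""
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray, fs: float | None = None) -> "SampledSignal":
        return SampledSignal(values, self.fs if fs is None else fs, self.label)


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the contact-BVP preprocessing chain.

    Defaults follow the benchmark's stated configuration: a 4th-order,
    19-frame Savitzky-Golay smoother and a 2nd-order Butterworth band-pass
    with a 0.7–7 Hz pass band, applied after resampling to 30.30 Hz.
    """

    savgol_order: int = 4
    savgol_window: int = 19
    bp_order: int = 2
    bp_low: float = 0.7
    bp_high: float = 7.0
    target_fs: float = 30.30

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise InvalidArgument(
                "savgol_window must be odd and greater than savgol_order"
            )
        if not (0 < self.bp_low < self.bp_high < self.target_fs / 2):
            raise InvalidArgument(
                "band edges must satisfy 0 < low < high < target_fs/2"
            )


def resample(signal: SampledSignal, target_fs: float) -> SampledSignal:
    """Resample to ``target_fs`` by Fourier (band-limited) interpolation.

    Duration is preserved to within one sample period; spectral content below
    the smaller Nyquist rate is preserved. Equal input and output rates return
    the signal unchanged.
    """
    if not (target_fs > 0):
        raise InvalidArgument(f"target_fs must be > 0, got {target_fs}")
    if len(signal) < 2:
        raise TooShortSignal("resampling requires at least 2 samples")
    if np.isclose(target_fs, signal.fs):
        return replace(signal, fs=float(target_fs))
    n_out = int(round(len(signal) * target_fs / signal.fs))
    if n_out < 1:
        raise TooShortSignal("target rate yields an empty signal")
    out = scipy.signal.resample(signal.values, n_out)
    return signal.with_values(out, fs=float(target_fs))


def savgol_smooth(signal: SampledSignal, order: int = 4, window: int = 19) -> SampledSignal:
    """Savitzky-Golay least-squares local-polynomial smoothing.

    Edges are handled by evaluating the edge-window interpolating polynomial
    (``mode="interp"``), so polynomials up to ``order`` pass through exactly.
    """
    if window % 2 == 0 or window <= order:
        raise InvalidArgument("window must be odd and greater than order")
    if len(signal) < window:
        raise TooShortSignal(
            f"signal of {len(signal)} samples is shorter than window {window}"
        )
    out = scipy.signal.savgol_filter(signal.values, window, order, mode="interp")
    return signal.with_values(out)


def butter_bandpass(
    signal: SampledSignal, low: float = 0.7, high: float = 7.0, order: int = 2
) -> SampledSignal:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    Forward-backward application doubles the effective order but leaves peak
    timing unshifted, which downstream peak-position comparisons rely on.
    """
    nyq = signal.fs / 2
    if not (0 < low < high < nyq):
        raise InvalidArgument(
            f"band [{low}, {high}] Hz must lie strictly inside (0, {nyq}) Hz"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=signal.fs, output="sos")
    padlen = min(len(signal) - 1, 3 * (2 * order + 1))
    out = scipy.signal.sosfiltfilt(sos, signal.values, padlen=padlen)
    return signal.with_values(out)


def preprocess_bvp(signal: SampledSignal, cfg: FilterConfig = FilterConfig()) -> SampledSignal:
    """Full contact-BVP chain: resample → Savitzky-Golay → Butterworth band-pass."""
    out = resample(signal, cfg.target_fs)
    out = savgol_smooth(out, cfg.savgol_order, cfg.savgol_window)
    out = butter_bandpass(out, cfg.bp_low, cfg.bp_high, cfg.bp_order)
    return out
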