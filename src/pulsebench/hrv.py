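"""RR intervals and heart-rate-variability features.

Features are computed from the series of inter-beat (RR) intervals between
*valid* adjacent pulsatile peaks, in milliseconds:

time domain
    ``mean_hr = 60000 / mean(RR)`` (bpm), ``ibi = mean(RR)`` (ms),
    ``rmssd`` — root mean square of the N−1 successive differences,
    ``sdnn`` — sample standard deviation (N−1 denominator),
    ``nni20``/``nni50`` — counts of successive-difference pairs exceeding
    20/50 ms, plus their proportions ``pnn20``/``pnn50``.
frequency domain
    The tachogram (RR as a function of cumulative beat time) is cubically
    interpolated onto a uniform 4 Hz grid and its Welch power spectral
    density integrated over the low-frequency band [0.04, 0.15] Hz and the
    high-frequency band [0.15, 0.4] Hz; RR is taken in seconds, so band
    powers are in s².
nonlinear
    Sample entropy with embedding m = 2 and tolerance r = 0.2·SDNN
    (Chebyshev distance, self-matches excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.interpolate
import scipy.signal

from .errors import (
    DegenerateSeries,
    InsufficientData,
    InvalidArgument,
    UndefinedMetric,
)
from .peaks import PeakValidation

__all__ = [
    "RRSeries",
    "rr_intervals",
    "time_domain_features",
    "sample_entropy",
    "frequency_features",
    "feature_vector",
    "sliding_hr",
    "FEATURE_REGISTRY",
    "register_feature",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass(frozen=True)
class RRSeries:
    """Inter-beat intervals in milliseconds, all positive and finite."""

    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_ms, dtype=float)
        if rr.ndim != 1:
            raise InvalidArgument("rr_ms must be 1-D")
        if rr.size and (not np.all(np.isfinite(rr)) or np.any(rr <= 0)):
            raise InvalidArgument("RR intervals must be positive and finite")
        object.__setattr__(self, "rr_ms", rr)

    def __len__(self) -> int:
        return self.rr_ms.size

    @property
    def span_s(self) -> float:
        """Total time covered by the intervals, in seconds."""
        return float(self.rr_ms.sum() / 1000.0)


def rr_intervals(v: PeakValidation) -> RRSeries:
    """RR intervals between adjacent valid peaks.

    An interval contributes only if both of its endpoint peaks are valid and
    consecutive in the detected sequence; pairs spanning an invalid peak are
    excluded rather than bridged.
    """
    valid = v.valid
    keep = valid[:-1] & valid[1:]
    rr = v.ibi_ms[keep]
    if rr.size < 2:
        raise InsufficientData(
            f"need >= 2 RR intervals from valid adjacent peaks, got {rr.size}"
        )
    return RRSeries(rr)


def time_domain_features(rr: RRSeries) -> dict[str, float]:
    """Time-domain features: mean_hr, ibi, rmssd, sdnn, nni20/pnn20, nni50/pnn50."""
    x = rr.rr_ms
    if x.size < 2:
        raise InsufficientData("time-domain features need >= 2 intervals")
    diffs = np.abs(np.diff(x))
    ibi = float(np.mean(x))
    return {
        "mean_hr": 60000.0 / ibi,
        "ibi": ibi,
        "rmssd": float(np.sqrt(np.sum(np.diff(x) ** 2) / (x.size - 1))),
        "sdnn": float(np.std(x, ddof=1)),
        "nni20": float(np.count_nonzero(diffs > 20.0)),
        "pnn20": float(np.count_nonzero(diffs > 20.0) / diffs.size),
        "nni50": float(np.count_nonzero(diffs > 50.0)),
        "pnn50": float(np.count_nonzero(diffs > 50.0) / diffs.size),
        "median_rr": float(np.median(x)),
        "cv_rr": float(np.std(x, ddof=1) / ibi),
    }


def sample_entropy(rr: RRSeries, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy: −ln(A/B) with templates of length m+1 and m.

    ``A`` and ``B`` count ordered template pairs (i ≠ j) whose Chebyshev
    distance is within ``r = r_frac · SDNN``. Returns ``inf`` when no
    (m+1)-length matches exist.
    """
    x = rr.rr_ms
    if m < 1:
        raise InvalidArgument("m must be >= 1")
    if x.size < m + 2:
        raise InsufficientData(f"sample entropy needs >= {m + 2} intervals")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise DegenerateSeries("sample entropy undefined for a constant series")
    r = r_frac * sd

    # common convention: both template sets limited to the first N - m vectors
    def count_limited(mm: int) -> int:
        n_tpl = x.size - m
        tpl = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_tpl]
        d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=2)
        return int(np.count_nonzero(d <= r) - n_tpl)

    B = count_limited(m)
    A = count_limited(m + 1)
    if B == 0:
        raise DegenerateSeries("no m-length template matches within tolerance")
    if A == 0:
        return float("inf")
    return float(-np.log(A / B))


def frequency_features(rr: RRSeries, grid_fs: float = 4.0) -> dict[str, float]:
    """Band powers of the interpolated tachogram: lf, hf (s²) and lf/hf.

    The RR series (seconds) is placed at cumulative beat times, cubically
    interpolated to a uniform ``grid_fs`` grid, de-trended by mean removal,
    and its Welch PSD integrated over the LF and HF bands.
    """
    x = rr.rr_ms / 1000.0  # seconds
    if rr.span_s < 60.0:
        raise InsufficientData(
            f"frequency features need >= 60 s of intervals, got {rr.span_s:.1f} s"
        )
    t = np.cumsum(x)
    spline = scipy.interpolate.CubicSpline(t, x)
    grid = np.arange(t[0], t[-1], 1.0 / grid_fs)
    y = spline(grid) - np.mean(spline(grid))
    nperseg = min(y.size, 256)
    freqs, psd = scipy.signal.welch(y, fs=grid_fs, nperseg=nperseg)

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[sel], freqs[sel])) if sel.sum() > 1 else 0.0

    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    if hf == 0:
        raise UndefinedMetric("LF/HF undefined: zero HF power")
    return {"lf": lf, "hf": hf, "lf_hf": lf / hf}


def _sampen_feature(rr: RRSeries) -> dict[str, float]:
    return {"sampen": sample_entropy(rr)}


def _total_power(rr: RRSeries) -> dict[str, float]:
    x = rr.rr_ms / 1000.0
    if rr.span_s < 60.0:
        raise InsufficientData("total power needs >= 60 s of intervals")
    return {"total_power": float(np.var(x, ddof=1))}


# Registry: group name -> callable(RRSeries) -> {feature: value}. Extend with
# register_feature(); a failing group reports its features as missing.
FEATURE_REGISTRY: dict[str, Callable[[RRSeries], dict[str, float]]] = {
    "time": time_domain_features,
    "nonlinear": _sampen_feature,
    "frequency": frequency_features,
    "spectral_extras": _total_power,
}


def register_feature(name: str, fn: Callable[[RRSeries], dict[str, float]]) -> None:
    """Register an additional feature group under ``name``."""
    FEATURE_REGISTRY[name] = fn


def feature_vector(rr: RRSeries) -> tuple[dict[str, float], dict[str, str]]:
    """Assemble all registered features.

    Returns ``(features, status)`` where ``status`` maps each registry group
    to ``"ok"`` or the reason it could not be computed. Uncomputable features
    are absent from ``features`` — never silently zero.
    """
    features: dict[str, float] = {}
    status: dict[str, str] = {}
    for group, fn in FEATURE_REGISTRY.items():
        try:
            features.update(fn(rr))
            status[group] = "ok"
        except (InsufficientData, DegenerateSeries, UndefinedMetric) as exc:
            status[group] = f"missing: {exc}"
    return features, status


def sliding_hr(
    v: PeakValidation,
    window_s: float = 30.0,
    stride_s: float = 1.0,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed heart rate: HR over valid RR intervals inside each window.

    Returns ``(t_center, hr_bpm)``; windows with fewer than two valid
    intervals yield NaN. ``duration_s`` defaults to the last peak time.
    """
    if duration_s is None:
        duration_s = float(v.peaks.times_s[-1]) if len(v.peaks) else 0.0
    if duration_s < window_s:
        raise InsufficientData(
            f"recording of {duration_s:.1f} s shorter than window {window_s} s"
        )
    times = v.peaks.times_s
    pair_ok = v.valid[:-1] & v.valid[1:] if len(v.peaks) > 1 else np.empty(0, bool)
    starts = np.arange(0.0, duration_s - window_s + 1e-9, stride_s)
    centers = starts + window_s / 2
    hr = np.full(starts.size, np.nan)
    for i, s0 in enumerate(starts):
        inside = pair_ok & (times[:-1] >= s0) & (times[1:] <= s0 + window_s)
        rr = v.ibi_ms[inside]
        if rr.size >= 2:
            hr[i] = 60000.0 / rr.mean()
    return centers, hr
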