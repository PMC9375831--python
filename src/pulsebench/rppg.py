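"""Remote-PPG core: ROI averaging, POS projection, and template filtering.

The camera-based pulse signal is recovered in three stages. Per-frame spatial
means of the red, green and blue channels over facial skin regions (forehead,
left cheek, right cheek) form an RGB trace. The plane-orthogonal-to-skin
(POS) projection then mixes the three channels into a single pulse signal:
inside each sliding window the channels are divided by their window means (so
static gain and slow illumination cancel), projected onto two chrominance
axes

    U = Gn - Bn
    V = Gn - Rn + Bn - Rn

and combined as ``U + alpha * V`` with ``alpha = std(U) / std(V)`` computed
per window; the de-meaned window signals are overlap-added. Finally a
matched-template convolutional filter suppresses residual noise: a single-beat
template is learned by averaging segments of the signal around its own
detected peaks and correlated against the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np

from .errors import FlatSignal, InsufficientPeaks, InvalidArgument
from .peaks import detect_peaks
from .signal import SampledSignal, butter_bandpass

__all__ = [
    "FrameStack",
    "ROISet",
    "RGBTrace",
    "PosConfig",
    "PeakTemplate",
    "LandmarkProvider",
    "StaticRoiProvider",
    "LandmarkRoiProvider",
    "extract_rgb_trace",
    "pos_transform",
    "build_peak_template",
    "conv_filter",
    "extract_rppg",
]


@dataclass(frozen=True)
class FrameStack:
    """A sequence of H×W×3 color frames (channel order R, G, B) at ``fps``."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise InvalidArgument("frames must have shape (T, H, W, 3)")
        if frames.shape[0] < 1 or frames.shape[1] < 1 or frames.shape[2] < 1:
            raise InvalidArgument("frame stack must be non-empty")
        if not (self.fps > 0):
            raise InvalidArgument("fps must be > 0")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "fps", float(self.fps))

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class ROISet:
    """Named boolean pixel masks, one per skin region."""

    regions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        regions = {}
        for name, mask in self.regions.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.ndim != 2:
                raise InvalidArgument(f"ROI {name!r} mask must be 2-D")
            if not mask.any():
                raise InvalidArgument(f"ROI {name!r} mask is empty")
            regions[name] = mask
        object.__setattr__(self, "regions", regions)

    def names(self) -> list[str]:
        return list(self.regions)


@dataclass(frozen=True)
class RGBTrace:
    """Per-frame spatial-mean R/G/B series at the video frame rate."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.g, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if not (r.shape == g.shape == b.shape) or r.ndim != 1:
            raise InvalidArgument("r, g, b must be 1-D and equal length")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(g)) and np.all(np.isfinite(b))):
            raise InvalidArgument("trace values must be finite")
        if not (self.fs > 0):
            raise InvalidArgument("fs must be > 0")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.r.size

    def stacked(self) -> np.ndarray:
        """Channels as a (3, T) array in R, G, B order."""
        return np.vstack([self.r, self.g, self.b])


@dataclass(frozen=True)
class PosConfig:
    """POS windowing and ROI-combination settings.

    ``window_len`` is the sliding analysis interval in seconds (default 1.6 s,
    roughly one to two cardiac cycles); windows slide by one sample and are
    overlap-added. ``combine_rois`` selects whether the three ROI traces are
    averaged before the projection or projected independently and averaged
    after.
    """

    window_len: float = 1.6
    combine_rois: str = "mean_before_pos"

    def __post_init__(self) -> None:
        if not (self.window_len > 0):
            raise InvalidArgument("window_len must be > 0")
        if self.combine_rois not in ("mean_before_pos", "mean_after_pos"):
            raise InvalidArgument(
                "combine_rois must be 'mean_before_pos' or 'mean_after_pos'"
            )


@dataclass(frozen=True)
class PeakTemplate:
    """A single-beat template of odd length 2K+1, amplitude-normalized."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size % 2 == 0:
            raise InvalidArgument("template must be 1-D with odd length")
        if not np.all(np.isfinite(t)):
            raise InvalidArgument("template values must be finite")
        peak = np.max(np.abs(t))
        if peak > 0:
            t = t / peak
        object.__setattr__(self, "t", t)

    @property
    def K(self) -> int:
        return (self.t.size - 1) // 2

    def __len__(self) -> int:
        return self.t.size


class LandmarkProvider(Protocol):
    """Pluggable facial-landmark backend.

    Given one frame, returns named landmark points as (row, col) pixel
    coordinates. At minimum the keys ``left_eyebrow``, ``right_eyebrow``,
    ``left_eye``, ``right_eye`` and ``nose_tip`` must be present.
    """

    def landmarks(self, frame: np.ndarray) -> Mapping[str, tuple[float, float]]: ...


class StaticRoiProvider:
    """Fixed-rectangle ROIs for patch videos with a known layout.

    ``regions`` maps names to ``(row0, row1, col0, col1)`` half-open bounds.
    When omitted, three equal horizontal bands of the frame are used as
    forehead / left cheek / right cheek stand-ins.
    """

    def __init__(self, regions: Mapping[str, tuple[int, int, int, int]] | None = None):
        self.regions = dict(regions) if regions is not None else None

    def rois(self, frame_shape: tuple[int, int]) -> ROISet:
        h, w = frame_shape
        regions = self.regions
        if regions is None:
            third = max(h // 3, 1)
            regions = {
                "forehead": (0, third, 0, w),
                "left_cheek": (third, 2 * third, 0, w // 2 or 1),
                "right_cheek": (third, 2 * third, w // 2 or 1, w),
            }
        masks = {}
        for name, (r0, r1, c0, c1) in regions.items():
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise InvalidArgument(f"ROI {name!r} bounds outside frame {frame_shape}")
            mask = np.zeros((h, w), dtype=bool)
            mask[r0:r1, c0:c1] = True
            masks[name] = mask
        return ROISet(masks)


class LandmarkRoiProvider:
    """Geometric forehead/cheek ROIs constructed from facial landmarks.

    The forehead is a rectangle spanning the inter-eyebrow width, extending
    upward by half the eyebrow-to-nose distance (hairline proxy); each cheek
    is a box below the corresponding eye, laterally bounded by the eye and
    the nose column.
    """

    def __init__(self, backend: LandmarkProvider):
        self.backend = backend

    def rois(self, frame: np.ndarray) -> ROISet:
        pts = self.backend.landmarks(frame)
        h, w = frame.shape[:2]
        lb, rb = pts["left_eyebrow"], pts["right_eyebrow"]
        le, re_ = pts["left_eye"], pts["right_eye"]
        nose = pts["nose_tip"]
        brow_y = (lb[0] + rb[0]) / 2
        face_h = max(nose[0] - brow_y, 4.0)

        def rect(r0, r1, c0, c1):
            r0, r1 = int(np.clip(r0, 0, h - 1)), int(np.clip(r1, 1, h))
            c0, c1 = int(np.clip(c0, 0, w - 1)), int(np.clip(c1, 1, w))
            if r1 <= r0 or c1 <= c0:
                raise InvalidArgument("degenerate landmark geometry")
            mask = np.zeros((h, w), dtype=bool)
            mask[r0:r1, c0:c1] = True
            return mask

        regions = {
            "forehead": rect(brow_y - 0.5 * face_h, brow_y, min(lb[1], rb[1]), max(lb[1], rb[1])),
            "left_cheek": rect(le[0] + 0.2 * face_h, nose[0], le[1], nose[1]),
            "right_cheek": rect(re_[0] + 0.2 * face_h, nose[0], nose[1], re_[1]),
        }
        return ROISet(regions)


def extract_rgb_trace(frames: FrameStack, rois: ROISet) -> dict[str, RGBTrace]:
    """Spatially average each channel over each ROI mask, per frame."""
    h, w = frames.frame_shape
    traces: dict[str, RGBTrace] = {}
    for name, mask in rois.regions.items():
        if mask.shape != (h, w):
            raise InvalidArgument(
                f"ROI {name!r} shape {mask.shape} does not match frames {(h, w)}"
            )
        roi_pixels = frames.frames[:, mask, :]  # (T, n_pixels, 3)
        means = roi_pixels.mean(axis=1)
        traces[name] = RGBTrace(means[:, 0], means[:, 1], means[:, 2], frames.fps)
    return traces


def pos_transform(trace: RGBTrace, cfg: PosConfig = PosConfig()) -> SampledSignal:
    """POS projection of an RGB trace into a single-channel pulse signal.

    Sliding windows of ``cfg.window_len`` seconds (stride one sample) are
    mean-normalized per channel, projected onto the two POS chrominance axes,
    combined with the per-window alpha weighting, de-meaned and overlap-added.
    Windows with a non-positive channel mean are skipped (degenerate);
    windows where ``std(V)`` vanishes use ``alpha = 0``. Output has the
    trace's length and rate.
    """
    n = len(trace)
    w = int(round(cfg.window_len * trace.fs))
    if w < 3:
        raise InvalidArgument(
            f"window of {w} samples too short; need window_len*fs >= 3"
        )
    if n < w:
        raise InvalidArgument(f"trace of {n} samples shorter than window {w}")

    C = trace.stacked()  # (3, n)
    win = np.lib.stride_tricks.sliding_window_view(C, w, axis=1)  # (3, n-w+1, w)
    mu = win.mean(axis=2)  # (3, n-w+1)
    ok = np.all(mu > 0, axis=0)
    if not ok.any():
        raise FlatSignal("all POS windows degenerate (non-positive channel mean)")

    with np.errstate(divide="ignore", invalid="ignore"):
        Cn = win / mu[:, :, None]
    U = Cn[1] - Cn[2]
    V = Cn[1] - 2.0 * Cn[0] + Cn[2]
    sU = U.std(axis=1)
    sV = V.std(axis=1)
    alpha = np.where(sV > 0, sU / np.where(sV > 0, sV, 1.0), 0.0)
    hwin = U + alpha[:, None] * V
    hwin = hwin - hwin.mean(axis=1, keepdims=True)
    hwin[~ok] = 0.0

    out = np.zeros(n)
    for k in range(w):  # overlap-add, vectorized over window starts
        out[k : k + hwin.shape[0]] += hwin[:, k]
    return SampledSignal(out, trace.fs, label="rPPG")


def build_peak_template(
    signal: SampledSignal,
    K: int | None = None,
    bp_low: float = 0.7,
    bp_high: float = 7.0,
) -> PeakTemplate:
    """Learn a single-beat template by averaging peak-centered segments.

    Peaks are detected on a band-passed (0.7–7 Hz) copy of the signal; for
    each peak with full 2K+1-sample support, the raw-signal segment centered
    on it is collected, the segments are averaged and amplitude-normalized.
    ``K`` defaults to half the median inter-peak distance, so the template
    spans about one beat.
    """
    x = signal.values
    if x.std() == 0:
        raise InsufficientPeaks("flat signal has no detectable peaks")
    can_band = len(signal) > 21 and bp_high < signal.fs / 2
    banded = butter_bandpass(signal, bp_low, bp_high) if can_band else signal
    pk = detect_peaks(banded)
    if len(pk) < 2:
        raise InsufficientPeaks(f"need >= 2 detected peaks, got {len(pk)}")
    if K is None:
        K = max(1, int(round(np.median(np.diff(pk.indices)) / 2)))
    if K < 0:
        raise InvalidArgument("K must be >= 0")
    segments = [
        x[i - K : i + K + 1]
        for i in pk.indices
        if i - K >= 0 and i + K + 1 <= x.size
    ]
    if len(segments) < 2:
        raise InsufficientPeaks("fewer than 2 peaks with full template support")
    return PeakTemplate(np.mean(segments, axis=0))


def conv_filter(signal: SampledSignal, template: PeakTemplate) -> SampledSignal:
    """Correlate the signal with the beat template (matched filtering).

    ``out[n] = (1/(2K+1)) * sum_k signal[n+k] * t[k]`` for k = -K..K, with
    zero extension outside the signal so the output keeps the input length
    and peak positions stay time-aligned.
    """
    if len(template) > len(signal):
        raise InvalidArgument("template longer than signal")
    out = np.convolve(signal.values, template.t[::-1], mode="same") / len(template)
    return signal.with_values(out)


def extract_rppg(
    source: FrameStack | RGBTrace | Sequence[RGBTrace] | Mapping[str, RGBTrace],
    pos_cfg: PosConfig = PosConfig(),
    K: int | None = None,
    roi_provider: StaticRoiProvider | None = None,
) -> SampledSignal:
    """Full rPPG core: ROI traces → POS → band-pass → template filter.

    ``source`` may be a frame stack (ROIs from ``roi_provider``, default
    static bands), a single RGB trace, or several per-ROI traces. Per-ROI
    traces are combined according to ``pos_cfg.combine_rois``.
    """
    if isinstance(source, FrameStack):
        provider = roi_provider if roi_provider is not None else StaticRoiProvider()
        traces = list(extract_rgb_trace(source, provider.rois(source.frame_shape)).values())
    elif isinstance(source, RGBTrace):
        traces = [source]
    elif isinstance(source, Mapping):
        traces = list(source.values())
    else:
        traces = list(source)
    if not traces:
        raise InvalidArgument("no RGB traces supplied")
    fs = traces[0].fs
    if any(len(t) != len(traces[0]) or t.fs != fs for t in traces):
        raise InvalidArgument("per-ROI traces must share length and rate")

    if len(traces) == 1 or pos_cfg.combine_rois == "mean_before_pos":
        mean_trace = RGBTrace(
            np.mean([t.r for t in traces], axis=0),
            np.mean([t.g for t in traces], axis=0),
            np.mean([t.b for t in traces], axis=0),
            fs,
        )
        raw = pos_transform(mean_trace, pos_cfg)
    else:
        parts = [pos_transform(t, pos_cfg).values for t in traces]
        raw = SampledSignal(np.mean(parts, axis=0), fs, label="rPPG")

    if raw.values.std() == 0:
        raise FlatSignal("POS output is flat (constant or degenerate input)")
    banded = butter_bandpass(raw, 0.7, min(7.0, 0.45 * raw.fs)) if raw.fs > 2 else raw
    template = build_peak_template(banded, K=K)
    return conv_filter(banded, template)
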