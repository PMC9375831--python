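"""Seeded generators for ground-truthed pulse signals, pulsatile RGB traces,
patch frame stacks, and a full benchmark-shaped cohort.

The generators emulate the structure of the public benchmark recordings the
toolkit targets: 56 subjects (26 high-difficulty "test", 30 "ctrl") × three
tasks (T1 rest, T2 speech, T3 arithmetic), each task yielding a 3-minute
contact blood-volume-pulse recording at 64 Hz and a facial video at 35 FPS.
Beat-to-beat variability is an AR(1) Gaussian walk on the RR series; the
waveform is an asymmetric single-beat pulse (systolic peak plus dicrotic
hump) placed at the cumulative beat times. The optical model for video is
the one the POS projection assumes: a baseline skin tone modulated
multiplicatively by illumination, an additive pulsatile component strongest
in the green channel, and additive step/ramp motion transients.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgument
from .peaks import PeakSeries
from .rppg import FrameStack, RGBTrace
from .hrv import RRSeries
from .signal import SampledSignal, resample

__all__ = [
    "SynthConfig",
    "CohortConfig",
    "CohortRecord",
    "synth_ppg",
    "synth_rgb_trace",
    "synth_frames",
    "synth_cohort",
]

# baseline skin tone (R, G, B) and relative pulsatile strength per channel:
# pulsatile energy is strongest in green, weakest in red
SKIN_BASE = np.array([140.0, 110.0, 95.0])
PULSE_WEIGHTS = np.array([0.45, 1.0, 0.65])


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    ``hr_bpm``/``sdnn_ms`` set mean heart rate and RR variability;
    ``pulse_amplitude`` is the relative pulsatile modulation depth of the
    RGB channels; ``motion_amp``/``illum_amp`` scale motion transients and
    multiplicative illumination drift; ``noise_amp`` is white noise on the
    contact waveform (relative to unit pulse amplitude).
    """

    hr_bpm: float = 72.0
    sdnn_ms: float = 50.0
    duration_s: float = 180.0
    fs: float = 64.0
    video_fps: float = 35.0
    pulse_amplitude: float = 0.02
    motion_amp: float = 0.0
    illum_amp: float = 0.0
    noise_amp: float = 0.0
    rr_phi: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (42.0 <= self.hr_bpm <= 210.0):
            raise InvalidArgument("hr_bpm must lie in [42, 210]")
        if self.duration_s < 10.0:
            raise InvalidArgument("duration_s must be >= 10")
        if self.sdnn_ms < 0 or self.fs <= 0 or self.video_fps <= 0:
            raise InvalidArgument("sdnn_ms must be >= 0 and rates > 0")
        if not (0 <= self.rr_phi < 1):
            raise InvalidArgument("rr_phi must lie in [0, 1)")


def _pulse_shape(tau: np.ndarray, rr_s: float) -> np.ndarray:
    """Asymmetric beat: unit systolic peak at tau=0 plus a dicrotic hump."""
    s1 = 0.09 * rr_s
    s2 = 0.18 * rr_s
    d = 0.32 * rr_s
    return np.exp(-0.5 * (tau / s1) ** 2) + 0.35 * np.exp(-0.5 * ((tau - d) / s2) ** 2)


def synth_ppg(cfg: SynthConfig) -> tuple[SampledSignal, PeakSeries, RRSeries]:
    """Generate a contact-style PPG with known beat positions.

    RR intervals follow a stationary AR(1) process with mean ``60000/hr_bpm``
    and marginal standard deviation ``sdnn_ms``, clipped to the plausible
    42–210 bpm band; the waveform superposes one asymmetric pulse per beat
    and optional white noise. Returns the signal together with the
    ground-truth peak sample indices and RR series.
    """
    rng = np.random.default_rng(cfg.seed)
    ibi_ms = 60000.0 / cfg.hr_bpm
    n_beats = int(np.ceil(cfg.duration_s * 1000.0 / ibi_ms)) + 4
    phi = cfg.rr_phi
    sigma_e = cfg.sdnn_ms * np.sqrt(1.0 - phi**2)
    x = np.empty(n_beats)
    x[0] = rng.normal(0.0, cfg.sdnn_ms)
    innov = rng.normal(0.0, sigma_e, size=n_beats - 1)
    for i in range(1, n_beats):
        x[i] = phi * x[i - 1] + innov[i - 1]
    rr = np.clip(ibi_ms + x, 300.0, 1400.0)

    t_beats = (np.cumsum(rr) - rr[0]) / 1000.0 + 0.5  # first beat at 0.5 s
    keep = t_beats < cfg.duration_s - 0.3
    t_beats = t_beats[keep]
    rr_true = np.diff(t_beats) * 1000.0

    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    wave = np.zeros(n)
    for i, tb in enumerate(t_beats):
        rr_s = rr[min(i, rr.size - 1)] / 1000.0
        lo = max(0, int((tb - 0.6 * rr_s) * cfg.fs))
        hi = min(n, int((tb + 0.9 * rr_s) * cfg.fs) + 1)
        wave[lo:hi] += _pulse_shape(t[lo:hi] - tb, rr_s)
    if cfg.noise_amp > 0:
        wave = wave + rng.normal(0.0, cfg.noise_amp, size=n)

    pos = t_beats * cfg.fs
    peak_idx = np.round(pos).astype(np.int64)
    inside = (peak_idx >= 0) & (peak_idx < n)
    peak_idx = peak_idx[inside]
    offsets = pos[inside] - peak_idx  # exact beat times, sub-sample
    return (
        SampledSignal(wave, cfg.fs, label="PPG"),
        PeakSeries(peak_idx, cfg.fs, offsets=offsets),
        RRSeries(rr_true),
    )


def synth_rgb_trace(ppg: SampledSignal, cfg: SynthConfig) -> RGBTrace:
    """Embed a pulse into a skin-toned RGB trace at the video frame rate.

    ``channel = base · (1 + illum(t)) + pulse_amplitude · base · w_c · ppg(t)
    + motion(t)`` where illumination drifts sinusoidally at ~0.3 Hz, the
    pulse weights ``w_c`` favor green, and motion transients are seeded
    step/ramp events common to all channels.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    vid = resample(ppg, cfg.video_fps)
    peak = np.max(np.abs(vid.values))
    pulse = vid.values / peak if peak > 0 else vid.values
    n = pulse.size
    t = np.arange(n) / cfg.video_fps

    illum = cfg.illum_amp * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    motion = np.zeros(n)
    if cfg.motion_amp > 0:
        n_events = rng.poisson(cfg.duration_s / 20.0)
        for _ in range(n_events):
            at = rng.integers(0, n)
            amp = cfg.motion_amp * rng.normal() * SKIN_BASE.mean() * 0.1
            if rng.random() < 0.5:
                motion[at:] += amp  # step
            else:
                ramp_len = int(rng.uniform(0.5, 3.0) * cfg.video_fps)
                seg = min(ramp_len, n - at)
                motion[at : at + seg] += amp * np.linspace(0, 1, seg)
                motion[at + seg :] += amp

    channels = []
    for c in range(3):
        channels.append(
            SKIN_BASE[c] * (1.0 + illum)
            + cfg.pulse_amplitude * SKIN_BASE[c] * PULSE_WEIGHTS[c] * pulse
            + motion
        )
    return RGBTrace(channels[0], channels[1], channels[2], cfg.video_fps)


def synth_frames(
    trace: RGBTrace,
    resolution: tuple[int, int] = (32, 32),
    pixel_noise: float = 0.0,
    seed: int = 0,
) -> FrameStack:
    """Render a trace as flat patch frames whose channel means equal the trace."""
    h, w = resolution
    if h < 1 or w < 1:
        raise InvalidArgument("resolution must be positive")
    rng = np.random.default_rng(seed)
    n = len(trace)
    frames = np.empty((n, h, w, 3))
    stacked = trace.stacked()  # (3, n)
    for c in range(3):
        frames[..., c] = stacked[c][:, None, None]
    if pixel_noise > 0:
        noise = rng.normal(0.0, pixel_noise, size=frames.shape)
        frames += noise - noise.mean(axis=(1, 2), keepdims=True)  # keep means exact
    return FrameStack(frames, trace.fs)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings.

    ``stress_effect_sd`` scales, in units of the between-subject standard
    deviation of each generator parameter, how far stressed records (test
    group, tasks T2/T3) are shifted: heart rate up, RR variability down,
    RR-series smoothness up (lowering short-term irregularity and hence
    NNi20 and sample entropy).
    """

    n_test: int = 26
    n_ctrl: int = 30
    duration_s: float = 180.0
    stress_effect_sd: float = 0.5
    include_rgb: bool = False
    hr_mean: float = 74.0
    hr_sd: float = 7.0
    sdnn_mean: float = 50.0
    sdnn_sd: float = 12.0
    phi_base: float = 0.7
    phi_sd: float = 0.08
    noise_amp: float = 0.0
    task_motion: tuple[float, float, float] = (0.0, 0.6, 0.6)
    task_illum: tuple[float, float, float] = (0.0, 0.15, 0.15)

    def __post_init__(self) -> None:
        if self.n_test + self.n_ctrl < 2:
            raise InvalidArgument("need at least 2 subjects")


@dataclass(frozen=True)
class CohortRecord:
    """One (subject, task) recording with full ground truth."""

    subject: str
    task: str
    group: str
    bvp: SampledSignal
    true_peaks: PeakSeries | None = None
    true_rr: RRSeries | None = None
    cfg: SynthConfig | None = None
    rgb: RGBTrace | None = None


def synth_cohort(
    cfg: CohortConfig = CohortConfig(), seed: int = 0
) -> tuple[pd.DataFrame, dict[tuple[str, str], CohortRecord]]:
    """Generate a full cohort: manifest plus per-(subject, task) records.

    The manifest has one row per (subject, task) with columns ``subject``,
    ``task``, ``group``. Group membership is a seeded shuffle of
    ``n_test`` + ``n_ctrl`` subjects. T1 records use resting parameters and
    no artifacts; T2/T3 add motion/illumination artifacts and a small
    activity HR increase; test-group T2/T3 records additionally receive the
    configured stress-effect shifts.
    """
    rng = np.random.default_rng(seed)
    n_sub = cfg.n_test + cfg.n_ctrl
    groups = np.array(["test"] * cfg.n_test + ["ctrl"] * cfg.n_ctrl)
    rng.shuffle(groups)
    subjects = [f"s{i + 1:02d}" for i in range(n_sub)]

    rows = []
    records: dict[tuple[str, str], CohortRecord] = {}
    for si, (subject, group) in enumerate(zip(subjects, groups)):
        hr0 = float(np.clip(rng.normal(cfg.hr_mean, cfg.hr_sd), 55.0, 100.0))
        sdnn0 = float(np.clip(rng.normal(cfg.sdnn_mean, cfg.sdnn_sd), 20.0, 90.0))
        phi0 = float(np.clip(rng.normal(cfg.phi_base, cfg.phi_sd), 0.3, 0.92))
        for ti, task in enumerate(("T1", "T2", "T3")):
            hr = hr0 + (4.0 if task != "T1" else 0.0)
            sdnn = sdnn0
            phi = phi0
            stressed = group == "test" and task != "T1"
            if stressed:
                hr += cfg.stress_effect_sd * cfg.hr_sd
                sdnn -= cfg.stress_effect_sd * cfg.sdnn_sd
                phi = min(phi + cfg.stress_effect_sd * cfg.phi_sd * 2.0, 0.92)
            rec_cfg = SynthConfig(
                hr_bpm=float(np.clip(hr, 45.0, 200.0)),
                sdnn_ms=float(np.clip(sdnn, 5.0, 150.0)),
                duration_s=cfg.duration_s,
                motion_amp=cfg.task_motion[ti],
                illum_amp=cfg.task_illum[ti],
                noise_amp=cfg.noise_amp,
                rr_phi=phi,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            bvp, true_peaks, true_rr = synth_ppg(rec_cfg)
            rgb = synth_rgb_trace(bvp, rec_cfg) if cfg.include_rgb else None
            records[(subject, task)] = CohortRecord(
                subject, task, group, bvp, true_peaks, true_rr, rec_cfg, rgb
            )
            rows.append({"subject": subject, "task": task, "group": group})
    return pd.DataFrame(rows), records
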