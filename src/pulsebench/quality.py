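"""Contact-vs-remote evaluation: peak matching, confusion metrics, SNR, MAE,
and the signal-quality exclusion criteria.

A remote (camera) pulse signal is judged against the simultaneously recorded
contact signal, taken as ground truth (GT), purely through the positions of
pulsatile peaks: a GT peak found by the remote method within a tolerance is a
true positive, a remote peak with no GT counterpart a false positive, and a
missed GT peak a false negative. Recordings whose *GT* signal is itself
unusable are excluded before any comparison, using three gates: fraction of
GT peaks passing the validity rules (> 60%), spectral SNR of the GT signal
(> 4 dB), and a manual blacklist manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.signal

from .errors import DegenerateSignal, InvalidArgument
from .peaks import PeakSeries
from .signal import SampledSignal

__all__ = [
    "ConfusionCounts",
    "SampleQuality",
    "match_peaks",
    "classification_metrics",
    "snr_db",
    "mae",
    "apply_exclusion",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts; TN stays 0 for peak matching (no 'no-peak events')."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidArgument("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SampleQuality:
    """Per-recording GT quality gates and the resulting retention decision."""

    sample_id: str
    valid_fraction_gt: float
    snr_db: float
    manually_excluded: bool = False

    def retained(self, valid_thresh: float = 0.60, snr_thresh_db: float = 4.0) -> bool:
        return (
            self.valid_fraction_gt > valid_thresh
            and self.snr_db > snr_thresh_db
            and not self.manually_excluded
        )

    def exclusion_reasons(
        self, valid_thresh: float = 0.60, snr_thresh_db: float = 4.0
    ) -> list[str]:
        reasons = []
        if not (self.valid_fraction_gt > valid_thresh):
            reasons.append("valid_peaks")
        if not (self.snr_db > snr_thresh_db):
            reasons.append("snr")
        if self.manually_excluded:
            reasons.append("manual")
        return reasons


def match_peaks(gt: PeakSeries, pred: PeakSeries, tol_ms: float = 100.0) -> ConfusionCounts:
    """Greedy one-to-one nearest matching of predicted to GT peaks.

    Candidate (gt, pred) pairs within ``tol_ms`` are accepted in order of
    increasing time offset, each peak matched at most once. Matched pairs are
    TP; leftover predictions FP; leftover GT peaks FN. Always satisfies
    ``tp + fn = len(gt)`` and ``tp + fp = len(pred)``.
    """
    if tol_ms < 0:
        raise InvalidArgument("tolerance must be non-negative")
    t_gt = gt.times_s * 1000.0
    t_pred = pred.times_s * 1000.0
    if t_gt.size == 0 or t_pred.size == 0:
        return ConfusionCounts(tp=0, fp=t_pred.size, fn=t_gt.size)
    dt = np.abs(t_gt[:, None] - t_pred[None, :])
    gi, pi = np.nonzero(dt <= tol_ms)
    order = np.argsort(dt[gi, pi], kind="stable")
    used_gt = np.zeros(t_gt.size, dtype=bool)
    used_pred = np.zeros(t_pred.size, dtype=bool)
    tp = 0
    for k in order:
        i, j = gi[k], pi[k]
        if not used_gt[i] and not used_pred[j]:
            used_gt[i] = used_pred[j] = True
            tp += 1
    return ConfusionCounts(tp=tp, fp=int(t_pred.size - tp), fn=int(t_gt.size - tp))


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, specificity, F1 — as percentages.

    A metric whose denominator is zero is reported as NaN (flagged
    undefined), never as 0.
    """
    if c.total < 1:
        raise InvalidArgument("at least one count required")

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "precision": precision,
        "recall": recall,
        "specificity": ratio(c.tn, c.tn + c.fp),
        "f1": f1,
    }


def snr_db(
    signal: SampledSignal,
    ref_hr_hz: float,
    band: tuple[float, float] = (0.7, 7.0),
    half_width_hz: float = 0.1,
) -> float:
    """Spectral SNR: pulse-band power near the HR fundamental and its first
    harmonic versus the remaining 0.7–7 Hz power, in dB.

    The PSD is estimated by Welch periodogram; signal power is integrated in
    ``±half_width_hz`` around ``ref_hr_hz`` and ``2·ref_hr_hz`` (clipped to
    the analysis band), noise power over the rest of the band. Amplitude
    scaling cancels.
    """
    lo, hi = band
    if not (lo <= ref_hr_hz <= hi):
        raise InvalidArgument(f"ref_hr_hz {ref_hr_hz} outside band {band}")
    x = signal.values
    nperseg = min(x.size, int(round(20 * signal.fs)))  # ~0.05 Hz resolution
    freqs, psd = scipy.signal.welch(x, fs=signal.fs, nperseg=nperseg)
    in_band = (freqs >= lo) & (freqs <= hi)
    total = float(np.sum(psd[in_band]))
    if total <= 0:
        raise DegenerateSignal("zero power in the pulse band")
    sig_sel = np.zeros_like(in_band)
    for f0 in (ref_hr_hz, 2.0 * ref_hr_hz):
        sig_sel |= np.abs(freqs - f0) <= half_width_hz
    sig_sel &= in_band
    p_sig = float(np.sum(psd[sig_sel]))
    p_noise = total - p_sig
    if p_noise <= 0:
        return float("inf")
    if p_sig <= 0:
        return float("-inf")
    return float(10.0 * np.log10(p_sig / p_noise))


def mae(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean absolute error between two equal-length sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise InvalidArgument("sequences must be 1-D, non-empty and equal length")
    return float(np.mean(np.abs(a - b)))


def apply_exclusion(
    samples: Iterable[SampleQuality],
    valid_thresh: float = 0.60,
    snr_thresh_db: float = 4.0,
    blacklist: Iterable[str] = (),
) -> tuple[list[str], list[str], dict[str, list[str]]]:
    """Partition recordings into retained and excluded by the GT-quality gates.

    ``blacklist`` ids are treated as manually excluded in addition to any
    per-sample flag. Returns ``(retained_ids, excluded_ids, reasons)`` where
    ``reasons`` lists, per excluded id, which gates failed.
    """
    blackset = set(blacklist)
    retained: list[str] = []
    excluded: list[str] = []
    reasons: dict[str, list[str]] = {}
    for s in samples:
        if s.sample_id in blackset:
            s = SampleQuality(s.sample_id, s.valid_fraction_gt, s.snr_db, True)
        if s.retained(valid_thresh, snr_thresh_db):
            retained.append(s.sample_id)
        else:
            excluded.append(s.sample_id)
            reasons[s.sample_id] = s.exclusion_reasons(valid_thresh, snr_thresh_db)
    return retained, excluded, reasons
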