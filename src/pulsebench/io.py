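"""Readers and writers for the plain-text interchange formats.

Formats:

* BVP CSV, wearable dialect: optional first line with the recording start
  time, second line the sampling rate in Hz, then one sample per line
  (Empatica-E4 style); or a plain one-column CSV with the rate supplied by
  the caller.
* RGB-trace CSV: columns ``frame_index, roi, R, G, B``.
* rPPG/signal CSV: columns ``time_s, value``.
* Peak CSV: columns ``sample_index, time_s, valid``.
* Manifest CSV: columns ``subject, task, group``.
* Blacklist CSV: columns ``sample_id, reason`` (manual-quality exclusions).
* Key=value config files mirroring the dataclass configs.

Output files written by the CLI start with ``#``-comment header lines
recording the tool version, seed and thresholds; readers skip them.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgument
from .peaks import PeakValidation
from .rppg import RGBTrace
from .signal import FilterConfig, SampledSignal

__all__ = [
    "read_bvp_csv",
    "write_bvp_csv",
    "read_trace_csv",
    "write_trace_csv",
    "write_signal_csv",
    "read_signal_csv",
    "write_peaks_csv",
    "read_manifest",
    "read_blacklist",
    "read_filter_config",
]


def _strip_comments(path: Path) -> _io.StringIO:
    lines = [
        ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")
    ]
    return _io.StringIO("\n".join(lines))


def read_bvp_csv(path: str | Path, fs: float | None = None) -> SampledSignal:
    """Read a contact-BVP CSV.

    With ``fs=None`` the wearable dialect is assumed: the first one or two
    non-comment lines are the start time (optional) and the sampling rate,
    followed by one sample per line. With ``fs`` given, every non-comment
    line is a sample.
    """
    raw = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not raw:
        raise InvalidArgument(f"{path}: empty BVP file")
    if fs is not None:
        values = np.array([float(x.split(",")[0]) for x in raw])
        return SampledSignal(values, fs, label="BVP")
    # dialect: [start_time,] rate, samples...
    header_vals = [float(x.split(",")[0]) for x in raw[:2]]
    if len(raw) < 3:
        raise InvalidArgument(f"{path}: too few lines for wearable dialect")
    # heuristic: a plausible sampling rate lies in (0, 1000] Hz; anything
    # else in the first line (e.g. a unix start timestamp) is metadata
    if 0.0 < header_vals[0] <= 1000.0:
        rate = header_vals[0]
        body = raw[1:]
    else:
        rate = header_vals[1]
        body = raw[2:]
    values = np.array([float(x.split(",")[0]) for x in body])
    return SampledSignal(values, rate, label="BVP")


def write_bvp_csv(
    path: str | Path, signal: SampledSignal, start_time: float | None = None
) -> None:
    """Write the wearable dialect; the start-time line is optional."""
    with open(path, "w") as fh:
        if start_time is not None:
            fh.write(f"{start_time:.2f}\n")
        fh.write(f"{signal.fs:.2f}\n")
        np.savetxt(fh, signal.values, fmt="%.6f")


def read_trace_csv(path: str | Path, fps: float) -> dict[str, RGBTrace]:
    """Read per-ROI RGB traces (columns frame_index, roi, R, G, B)."""
    df = pd.read_csv(_strip_comments(Path(path)))
    required = {"frame_index", "roi", "R", "G", "B"}
    if not required.issubset(df.columns):
        raise InvalidArgument(f"{path}: trace CSV needs columns {sorted(required)}")
    traces = {}
    for roi, sub in df.groupby("roi"):
        sub = sub.sort_values("frame_index")
        traces[str(roi)] = RGBTrace(
            sub["R"].to_numpy(), sub["G"].to_numpy(), sub["B"].to_numpy(), fps
        )
    return traces


def write_trace_csv(path: str | Path, traces: dict[str, RGBTrace], header: str = "") -> None:
    frames = []
    for roi, tr in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "frame_index": np.arange(len(tr)),
                    "roi": roi,
                    "R": tr.r,
                    "G": tr.g,
                    "B": tr.b,
                }
            )
        )
    _write_with_header(path, pd.concat(frames, ignore_index=True), header)


def _write_with_header(path: str | Path, df: pd.DataFrame, header: str) -> None:
    with open(path, "w") as fh:
        for line in filter(None, header.splitlines()):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_signal_csv(path: str | Path, signal: SampledSignal, header: str = "") -> None:
    df = pd.DataFrame({"time_s": signal.times, "value": signal.values})
    _write_with_header(path, df, header)


def read_signal_csv(path: str | Path, label: str = "") -> SampledSignal:
    df = pd.read_csv(_strip_comments(Path(path)))
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise InvalidArgument(f"{path}: need >= 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return SampledSignal(df["value"].to_numpy(), fs, label=label)


def write_peaks_csv(path: str | Path, v: PeakValidation, header: str = "") -> None:
    df = pd.DataFrame(
        {
            "sample_index": v.peaks.indices,
            "time_s": v.peaks.times_s,
            "valid": v.valid.astype(int),
        }
    )
    _write_with_header(path, df, header)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_strip_comments(Path(path)))
    required = {"subject", "task", "group"}
    if not required.issubset(df.columns):
        raise InvalidArgument(f"{path}: manifest needs columns {sorted(required)}")
    return df


def read_blacklist(path: str | Path) -> list[str]:
    df = pd.read_csv(_strip_comments(Path(path)))
    if "sample_id" not in df.columns:
        raise InvalidArgument(f"{path}: blacklist needs a sample_id column")
    return df["sample_id"].astype(str).tolist()


def read_filter_config(path: str | Path) -> FilterConfig:
    """Read ``key = value`` lines mirroring the FilterConfig fields."""
    kwargs: dict[str, float | int] = {}
    int_fields = {"savgol_order", "savgol_window", "bp_order"}
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise InvalidArgument(f"bad config line: {ln!r}")
        key, val = (part.strip() for part in ln.split("=", 1))
        kwargs[key] = int(val) if key in int_fields else float(val)
    return FilterConfig(**kwargs)  # type: ignore[arg-type]
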