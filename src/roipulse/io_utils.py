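"""Readers and writers for the package's plain-text interchange formats.

Formats:
- landmark files: JSON-lines, one ``{"frame": i, "points": [[x, y] * 468]}``
  object per video frame;
- trace files: CSV with header ``frame,time_s,R,G,B,valid``;
- pulse files: CSV with header ``time_s,value,method``;
- HR files: CSV with header ``time_s,bpm,source`` (source is ``estimate``
  or ``reference``);
- metric records: CSV with header
  ``roi_index,roi_name,activity,participant,method,mae,pcc,snr[,acceptance_rate]``;
- ground-truth contact-PPG: CSV with header ``time_s,value``.

Frames are exchanged as directories of numbered PNG files plus a frame
rate; a frame provider is anything that yields (H, W, 3) uint8 arrays in
order, so codecs never enter the tested core.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .hr_estimation import HRSeries
from .roi_scheme import FaceMeshFrame, RGBTrace
from .rppg_methods import RPPGSignal
from .synthetic import TimeSeries


# landmarks -----------------------------------------------------------------

def write_landmarks(path, mesh_frames: Sequence[FaceMeshFrame]) -> None:
    with open(path, "w") as fh:
        for m in mesh_frames:
            fh.write(json.dumps(
                {"frame": int(m.frame_index), "points": np.round(m.landmarks, 3).tolist()}
            ) + "\n")


def read_landmarks(path) -> list[FaceMeshFrame]:
    frames = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                frames.append(FaceMeshFrame(obj["frame"], np.asarray(obj["points"], float)))
            except (KeyError, ValueError, TypeError) as exc:
                raise InputError(f"{path}:{lineno}: bad landmark record: {exc}") from exc
    if not frames:
        raise InputError(f"{path}: no landmark records")
    return frames


# traces --------------------------------------------------------------------

def write_trace(path, trace: RGBTrace) -> None:
    df = pd.DataFrame({
        "frame": np.arange(trace.n_frames),
        "time_s": trace.times,
        "R": trace.samples[:, 0],
        "G": trace.samples[:, 1],
        "B": trace.samples[:, 2],
        "valid": trace.valid_mask.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace(path, frame_rate: float | None = None) -> RGBTrace:
    df = pd.read_csv(path)
    for col in ("frame", "time_s", "R", "G", "B", "valid"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    if frame_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or np.median(dt) <= 0:
            raise InputError(f"{path}: cannot infer frame rate")
        frame_rate = 1.0 / float(np.median(dt))
    samples = df[["R", "G", "B"]].to_numpy(float)
    return RGBTrace(frame_rate, samples, df["valid"].to_numpy(bool))


# pulse / HR series ---------------------------------------------------------

def write_pulse(path, signal: RPPGSignal) -> None:
    pd.DataFrame({
        "time_s": signal.times,
        "value": signal.values,
        "method": signal.method_tag,
    }).to_csv(path, index=False, float_format="%.8f")


def write_hr(path, estimate: HRSeries | None = None,
             reference: HRSeries | None = None) -> None:
    parts = []
    if estimate is not None:
        parts.append(pd.DataFrame({
            "time_s": estimate.timestamps, "bpm": estimate.values,
            "source": "estimate",
        }))
    if reference is not None:
        parts.append(pd.DataFrame({
            "time_s": reference.timestamps, "bpm": reference.values,
            "source": "reference",
        }))
    if not parts:
        raise InputError("nothing to write")
    pd.concat(parts).to_csv(path, index=False, float_format="%.4f")


def read_hr(path, source: str = "reference") -> HRSeries:
    df = pd.read_csv(path)
    if "source" in df.columns:
        df = df[df["source"] == source]
    if df.empty:
        raise InputError(f"{path}: no {source!r} rows")
    return HRSeries(df["time_s"].to_numpy(float), df["bpm"].to_numpy(float))


def write_timeseries(path, series: TimeSeries) -> None:
    pd.DataFrame({"time_s": series.timestamps, "value": series.values}) \
        .to_csv(path, index=False, float_format="%.6f")


def read_timeseries(path) -> TimeSeries:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "value" not in df.columns:
        raise InputError(f"{path}: expected columns time_s,value")
    return TimeSeries(df["time_s"].to_numpy(float), df["value"].to_numpy(float))


# frames --------------------------------------------------------------------

def write_frames(directory, frames: np.ndarray) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(d / f"frame_{i:06d}.png", frame.astype(np.uint8))


def iter_frames(directory) -> Iterator[np.ndarray]:
    d = Path(directory)
    paths = sorted(d.glob("frame_*.png"))
    if not paths:
        raise InputError(f"{d}: no frame_*.png files")
    for p in paths:
        yield np.asarray(iio.imread(p))


# config echo ---------------------------------------------------------------

def echo_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise InputError(f"{path}: config must be a mapping")
    return out
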