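"""Readers and writers for frames, traces, annotations, and detections.

Plain-text/standard formats only: PNG or multi-page TIFF for frames,
headed CSV for traces/annotations/detections, JSON for reports.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .model import (
    CatheterLine,
    FrameSequence,
    GroundTruth,
    PhysioRecord,
    SensorDetection,
    SensorSet,
    TruthSensor,
    N_IMPEDANCE_CHANNELS,
    N_MANO_CHANNELS,
)

MANO_COLUMNS = [f"p{i:02d}" for i in range(1, N_MANO_CHANNELS + 1)]
IMPED_COLUMNS = [f"z{i:02d}" for i in range(1, N_IMPEDANCE_CHANNELS + 1)]


# ---------------------------------------------------------------- frames

def write_frames(seq: FrameSequence, path: str | Path, fmt: str = "auto") -> None:
    """Write a sequence as a multi-page TIFF (file path) or PNG directory."""
    path = Path(path)
    if fmt == "auto":
        fmt = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "png_dir"
    if fmt == "tiff":
        tifffile.imwrite(path, seq.frames)
    elif fmt == "png_dir":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(seq.frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
    else:
        raise ValueError(f"unknown frame format {fmt!r}")


def read_sequence(path: str | Path, fps: float) -> FrameSequence:
    """Read frames from a multi-page TIFF or a directory of PNG/TIFF files.

    Directory entries are taken in lexicographic order.  All frames must
    share one shape; timestamps are derived from ``fps``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        frames = []
        for p in files:
            try:
                img = iio.imread(p)
            except Exception as exc:
                raise ValueError(f"cannot read frame file {p.name}: {exc}") from exc
            if img.ndim == 3:  # collapse accidental RGB
                img = img[..., 0]
            frames.append(img)
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
        stack = np.stack(frames)
    elif path.exists():
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    else:
        raise FileNotFoundError(path)
    n = len(stack)
    return FrameSequence(frames=stack, fps=fps, timestamps=np.arange(n) / fps)


# ---------------------------------------------------------------- physio

def write_physio(rec: PhysioRecord, path: str | Path) -> None:
    t = rec.t0 + np.arange(rec.n_samples) / rec.rate
    df = pd.DataFrame({"time": t})
    for i, col in enumerate(MANO_COLUMNS):
        df[col] = rec.mano[i]
    for i, col in enumerate(IMPED_COLUMNS):
        df[col] = rec.imped[i]
    df.to_csv(path, index=False)


def read_physio(path: str | Path, expected_rate: float = 50.0, rate_tol: float = 0.5) -> PhysioRecord:
    """Read a wide physiology CSV (time + 36 manometry + 15 impedance columns).

    Validates the channel counts and that the sampling rate inferred from
    the time column is ``expected_rate`` within ``rate_tol``.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("physiology CSV must have a 'time' column")
    mano_cols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    imped_cols = [c for c in df.columns if c.startswith("z") and c[1:].isdigit()]
    if len(mano_cols) != N_MANO_CHANNELS:
        raise ValueError(
            f"expected {N_MANO_CHANNELS} manometry columns, found {len(mano_cols)}"
        )
    if len(imped_cols) != N_IMPEDANCE_CHANNELS:
        raise ValueError(
            f"expected {N_IMPEDANCE_CHANNELS} impedance columns, found {len(imped_cols)}"
        )
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) and (dt <= 0).any():
        raise ValueError("time column must be strictly increasing")
    rate = 1.0 / float(np.median(dt)) if len(dt) else expected_rate
    if abs(rate - expected_rate) > rate_tol:
        raise ValueError(
            f"sampling rate {rate:.2f} Hz differs from expected {expected_rate} Hz"
        )
    return PhysioRecord(
        mano=df[sorted(mano_cols)].to_numpy().T,
        imped=df[sorted(imped_cols)].to_numpy().T,
        rate=rate,
        t0=float(t[0]) if len(t) else 0.0,
    )


# ---------------------------------------------------------------- annotations

def write_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        {
            "frame": fi,
            "sensor_index": t.index,
            "row": t.row,
            "col": t.col,
            "occluded": int(t.occluded),
        }
        for fi, frame in enumerate(truth.per_frame)
        for t in frame
    ]
    pd.DataFrame(rows, columns=["frame", "sensor_index", "row", "col", "occluded"]).to_csv(
        path, index=False
    )


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    per_frame: list[list[TruthSensor]] = [[] for _ in range(n_frames)]
    for rec in df.itertuples():
        per_frame[int(rec.frame)].append(
            TruthSensor(
                index=int(rec.sensor_index),
                row=float(rec.row),
                col=float(rec.col),
                occluded=bool(rec.occluded),
            )
        )
    return GroundTruth(per_frame=per_frame)


# ---------------------------------------------------------------- detections

def write_detections(sensor_sets: list[SensorSet], path: str | Path) -> None:
    rows = [
        {
            "frame": fi,
            "sensor_index": s.index,
            "row": s.row,
            "col": s.col,
            "confidence": s.confidence,
            "inferred": int(s.inferred),
        }
        for fi, sset in enumerate(sensor_sets)
        for s in sset
    ]
    pd.DataFrame(
        rows, columns=["frame", "sensor_index", "row", "col", "confidence", "inferred"]
    ).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[SensorSet]:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    out = [SensorSet() for _ in range(n_frames)]
    for rec in df.itertuples():
        out[int(rec.frame)].sensors.append(
            SensorDetection(
                index=int(rec.sensor_index),
                row=float(rec.row),
                col=float(rec.col),
                arc=float("nan"),
                confidence=float(rec.confidence),
                inferred=bool(rec.inferred),
            )
        )
    return out


def write_lines(lines: list[CatheterLine], path: str | Path) -> None:
    rows = [
        {"frame": fi, "row": int(r), "col": float(c)}
        for fi, line in enumerate(lines)
        for r, c in zip(line.rows, line.cols)
    ]
    pd.DataFrame(rows, columns=["frame", "row", "col"]).to_csv(path, index=False)
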