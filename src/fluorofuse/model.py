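"""Shared in-memory containers for the detection and fusion pipeline.

Conventions used throughout the package:

* images are 2-D grayscale arrays indexed ``(row, col)`` with 0-based
  coordinates; frame indices are 0-based;
* a catheter line is stored one point per image row, top to bottom;
* sensor indices follow the catheter hardware numbering 1..36, with
  index 1 at the proximal (top) end of the catheter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_MANO_CHANNELS = 36
N_IMPEDANCE_CHANNELS = 15
PHYSIO_RATE_HZ = 50.0


@dataclass
class FrameSequence:
    """An ordered grayscale image sequence with acquisition timestamps."""

    frames: np.ndarray  # (n_frames, rows, cols)
    fps: float
    timestamps: np.ndarray  # seconds, shape (n_frames,)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Sequence duration in seconds (n_frames / fps)."""
        return len(self.frames) / self.fps


@dataclass
class CatheterLine:
    """Polyline tracing the catheter, one point per spanned image row.

    ``rows`` are strictly increasing consecutive integers; ``cols`` may be
    fractional (sub-pixel).  ``quality`` is the mean heatmap score along the
    line where it was measured, ``None`` for synthetic ground-truth lines.
    """

    rows: np.ndarray
    cols: np.ndarray
    quality: float | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=float)
        if self.rows.ndim != 1 or self.rows.shape != self.cols.shape:
            raise ValueError("rows and cols must be matching 1-D arrays")
        if len(self.rows) and np.any(np.diff(self.rows) != 1):
            raise ValueError("rows must be consecutive and strictly increasing")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.rows[0]), int(self.rows[-1])

    def arc(self) -> np.ndarray:
        """Cumulative arc length (px) at each stored point, starting at 0."""
        if len(self.rows) == 0:
            return np.zeros(0)
        seg = np.hypot(1.0, np.diff(self.cols))
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        a = self.arc()
        return float(a[-1]) if len(a) else 0.0

    def point_at_arc(self, s: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (row, col) at arc position(s) ``s`` from the top end."""
        a = self.arc()
        r = np.interp(s, a, self.rows.astype(float))
        c = np.interp(s, a, self.cols)
        return r, c

    def col_at_row(self, rows: np.ndarray | float) -> np.ndarray:
        return np.interp(rows, self.rows.astype(float), self.cols)


@dataclass
class SensorDetection:
    """A single numbered sensor center found (or inferred) in one frame."""

    index: int  # hardware sensor number, 1..36
    row: float
    col: float
    arc: float  # arc position along the catheter line, px from its top end
    confidence: float  # heatmap score in [-1, 1]
    inferred: bool = False


@dataclass
class SensorSet:
    """All sensors emitted for one frame."""

    sensors: list[SensorDetection] = field(default_factory=list)
    low_confidence: bool = False  # fewer than 3 supporting peaks

    def __len__(self) -> int:
        return len(self.sensors)

    def __iter__(self):
        return iter(self.sensors)

    def positions(self) -> np.ndarray:
        """(n, 2) array of (row, col) centers."""
        return np.array([[s.row, s.col] for s in self.sensors]).reshape(-1, 2)

    def indices(self) -> np.ndarray:
        return np.array([s.index for s in self.sensors], dtype=int)

    def by_index(self) -> dict[int, SensorDetection]:
        return {s.index: s for s in self.sensors}


@dataclass
class TruthSensor:
    """Ground-truth location of one sensor in one frame."""

    index: int
    row: float
    col: float
    occluded: bool = False


@dataclass
class GroundTruth:
    """Per-frame ground-truth sensor annotations."""

    per_frame: list[list[TruthSensor]]

    def __len__(self) -> int:
        return len(self.per_frame)

    def frame(self, i: int) -> list[TruthSensor]:
        return self.per_frame[i]

    def positions(self, i: int) -> np.ndarray:
        return np.array([[t.row, t.col] for t in self.per_frame[i]]).reshape(-1, 2)


@dataclass
class PhysioRecord:
    """Synchronized manometry (36 ch, mmHg) and impedance (15 ch, Ohm) traces.

    Both share one clock at ``rate`` samples/s starting at ``t0`` relative to
    the frame-sequence time origin.
    """

    mano: np.ndarray  # (36, n_samples), mmHg
    imped: np.ndarray  # (15, n_samples), Ohm
    rate: float = PHYSIO_RATE_HZ
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.mano = np.asarray(self.mano, dtype=float)
        self.imped = np.asarray(self.imped, dtype=float)
        if self.mano.shape[0] != N_MANO_CHANNELS:
            raise ValueError(
                f"expected {N_MANO_CHANNELS} manometry channels, got {self.mano.shape[0]}"
            )
        if self.imped.shape[0] != N_IMPEDANCE_CHANNELS:
            raise ValueError(
                f"expected {N_IMPEDANCE_CHANNELS} impedance channels, got {self.imped.shape[0]}"
            )
        if not (np.isfinite(self.mano).all() and np.isfinite(self.imped).all()):
            raise ValueError("physiological traces must be finite")

    @property
    def n_samples(self) -> int:
        return self.mano.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate
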