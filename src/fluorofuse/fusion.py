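"""Projection of manometry and impedance values onto detected sensors.

Frames and physiological traces share one clock, so each frame simply
takes the nearest 50 Hz sample.  Pressures are projected as a colored
ribbon drawn along the catheter line (values interpolated between sensor
centers for a continuous band); impedance channels, each measured between
a pair of sensors (every second sensor starting from the fourth), are
drawn as a second ribbon offset laterally.  Colors follow a Clouse-plot
style blue-to-red ramp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import matplotlib
import numpy as np

from .model import CatheterLine, N_IMPEDANCE_CHANNELS, PhysioRecord, SensorSet


@dataclass
class ColorScale:
    """Monotone mapping from a physiological value to a ramp color."""

    value_min: float
    value_max: float
    cmap: str = "jet"  # blue -> green -> yellow -> red, Clouse-plot style
    log: bool = False

    def __post_init__(self) -> None:
        if not self.value_min < self.value_max:
            raise ValueError("value_min must be < value_max")
        if self.log and self.value_min <= 0:
            raise ValueError("log scaling requires a positive value_min")

    def normalize(self, values: np.ndarray | float) -> np.ndarray:
        v = np.clip(np.asarray(values, dtype=float), self.value_min, self.value_max)
        if self.log:
            return (np.log10(v) - np.log10(self.value_min)) / (
                np.log10(self.value_max) - np.log10(self.value_min)
            )
        return (v - self.value_min) / (self.value_max - self.value_min)

    def rgb(self, values: np.ndarray | float) -> np.ndarray:
        """uint8 RGB color(s) for value(s); out-of-range values are clamped."""
        cm = matplotlib.colormaps[self.cmap]
        out = cm(np.atleast_1d(self.normalize(values)), bytes=True)[:, :3]
        return out if np.ndim(values) else out[0]


#: Display defaults: clinical manometry range and log-scaled impedance.
DEFAULT_MANO_SCALE = ColorScale(-10.0, 150.0)
DEFAULT_IMPED_SCALE = ColorScale(50.0, 2000.0, log=True)


@dataclass
class OverlayFrame:
    """RGB frame with the physiology ribbons rendered onto it."""

    image: np.ndarray  # (rows, cols, 3) uint8
    mano_scale: ColorScale = field(default_factory=lambda: DEFAULT_MANO_SCALE)
    imped_scale: ColorScale = field(default_factory=lambda: DEFAULT_IMPED_SCALE)


def sync_sample_index(frame_time: float, physio_rate: float, n_samples: int) -> int:
    """Nearest physiology sample for a frame timestamp, clipped to the record.

    At 50 Hz against <= 15 fps frames the nearest-sample error is <= 10 ms,
    so no temporal interpolation of the traces is needed.
    """
    if frame_time < 0:
        raise ValueError("frame_time must be >= 0")
    idx = int(round(frame_time * physio_rate))
    if idx >= n_samples:
        warnings.warn(
            f"frame time {frame_time:.3f}s is beyond the physiology record; "
            "using the last sample",
            stacklevel=2,
        )
        idx = n_samples - 1
    return idx


def impedance_span(channel: int) -> tuple[int, int]:
    """Sensor pair an impedance channel is measured between.

    The 15 channels sit between every second sensor starting from the
    fourth: channel k spans sensors (2 + 2k, 4 + 2k), i.e. channel 1 spans
    (4, 6) and channel 15 spans (32, 34).
    """
    if not 1 <= channel <= N_IMPEDANCE_CHANNELS:
        raise ValueError(f"impedance channel must be in 1..{N_IMPEDANCE_CHANNELS}")
    return 2 + 2 * channel, 4 + 2 * channel


def interpolate_along_catheter(
    arcs: np.ndarray, values: np.ndarray, step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear value profile between valued sensors, 1 px arc steps.

    Returns (sample_arcs, sample_values) restricted to the span between the
    outermost valued sensors; no extrapolation beyond them.
    """
    arcs = np.asarray(arcs, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(arcs) < 2:
        raise ValueError("need at least two valued sensors to interpolate")
    order = np.argsort(arcs)
    arcs, values = arcs[order], values[order]
    s = np.arange(arcs[0], arcs[-1] + step / 2.0, step)
    return s, np.interp(s, arcs, values)


def _line_geometry(line: CatheterLine, s: np.ndarray):
    """(rows, cols, normal) of the line at arc positions ``s``."""
    arc = line.arc()
    rows = np.interp(s, arc, line.rows.astype(float))
    cols = np.interp(s, arc, line.cols)
    tr = np.gradient(rows)
    tc = np.gradient(cols)
    n = np.hypot(tr, tc)
    n[n == 0] = 1.0
    # unit normal pointing to the catheter's right
    return rows, cols, (-tc / n, tr / n)


def _paint_band(
    img: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    normal: tuple[np.ndarray, np.ndarray],
    colors: np.ndarray,
    width: float,
    lateral_offset: float = 0.0,
) -> None:
    nr, nc = normal
    offsets = np.linspace(-width / 2.0, width / 2.0, max(2, int(np.ceil(2 * width))))
    h, w = img.shape[:2]
    for o in offsets:
        rr = np.round(rows + (lateral_offset + o) * nr).astype(int)
        cc = np.round(cols + (lateral_offset + o) * nc).astype(int)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[ok], cc[ok]] = colors[ok]


def render_overlay(
    frame: np.ndarray,
    line: CatheterLine,
    sensors: SensorSet,
    physio: PhysioRecord,
    frame_time: float,
    mano_scale: ColorScale | None = None,
    imped_scale: ColorScale | None = None,
    ribbon_width: float = 8.0,
    imped_offset: float = 14.0,
    imped_width: float = 6.0,
) -> OverlayFrame:
    """Render the two physiology ribbons onto a frame.

    Pure function of its inputs: re-rendering is bit-identical.  Pixels
    outside the ribbons are untouched.  Inferred sensors are rendered
    exactly like detected ones.  The pixel at each sensor center carries
    exactly ``colormap(clamped value)`` for that sensor's synchronized
    pressure sample.
    """
    mano_scale = mano_scale if mano_scale is not None else DEFAULT_MANO_SCALE
    imped_scale = imped_scale if imped_scale is not None else DEFAULT_IMPED_SCALE
    if len(sensors) < 2:
        raise ValueError("need at least two detected sensors to render an overlay")
    idx = sync_sample_index(frame_time, physio.rate, physio.n_samples)

    gray = np.asarray(frame)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    if gray.dtype != np.uint8:
        gray = np.clip(gray, 0, 255).astype(np.uint8)
    img = np.stack([gray] * 3, axis=-1)

    by_index = sensors.by_index()
    for s in sensors:
        if not 1 <= s.index <= physio.mano.shape[0]:
            raise ValueError(f"no manometry channel for sensor index {s.index}")

    # --- manometry ribbon along the catheter ---
    arcs = np.array([s.arc for s in sensors])
    values = np.array([physio.mano[s.index - 1, idx] for s in sensors])
    samp_s, samp_v = interpolate_along_catheter(arcs, values)
    rows, cols, normal = _line_geometry(line, samp_s)
    _paint_band(img, rows, cols, normal, mano_scale.rgb(samp_v), ribbon_width)

    # --- impedance ribbon, laterally offset, spanning channel sensor pairs ---
    ch_arcs, ch_vals = [], []
    for ch in range(1, N_IMPEDANCE_CHANNELS + 1):
        a, b = impedance_span(ch)
        if a in by_index and b in by_index:
            if ch > physio.imped.shape[0]:
                raise ValueError(f"physiology record has no impedance channel {ch}")
            ch_arcs.append(0.5 * (by_index[a].arc + by_index[b].arc))
            ch_vals.append(physio.imped[ch - 1, idx])
    if len(ch_arcs) >= 2:
        samp_s, samp_v = interpolate_along_catheter(np.array(ch_arcs), np.array(ch_vals))
        rows, cols, normal = _line_geometry(line, samp_s)
        _paint_band(
            img, rows, cols, normal, imped_scale.rgb(samp_v), imped_width, imped_offset
        )

    # exact colormap color at each sensor center (detected and inferred alike)
    h, w = gray.shape
    for s in sensors:
        rr, cc = int(round(s.row)), int(round(s.col))
        if 0 <= rr < h and 0 <= cc < w:
            img[rr, cc] = mano_scale.rgb(physio.mano[s.index - 1, idx])

    return OverlayFrame(image=img, mano_scale=mano_scale, imped_scale=imped_scale)
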