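"""Single-sensor localization and numbering along an accepted catheter line.

Stage two of the detector: the single-sensor NCC heatmap is sampled along
the catheter line at 1 px arc steps, peaks are picked under a minimum
separation constraint, and the peaks are snapped to a regular arc-length
grid at the locally estimated inter-sensor spacing.  Grid slots without a
supporting peak become *inferred* sensors (occluded or low contrast);
numbering runs from the visible catheter end, which is the only reliable
reference for which of the 36 hardware sensors are in frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .catheter import ncc_heatmap  # re-exported convenience
from .model import CatheterLine, SensorDetection, SensorSet
from .templates import Template

__all__ = [
    "ArcProfile",
    "SensorParams",
    "sensor_heatmap",
    "profile_along_line",
    "detect_peaks",
    "regularize_and_number",
]


@dataclass
class SensorParams:
    peak_floor: float = 0.45  # minimum NCC score for a sensor peak
    min_sep_frac: float = 0.6  # peak separation >= this fraction of spacing
    spacing_tol_frac: float = 0.2  # clip the spacing estimate to nominal +- this
    margin_frac: float = 0.35  # no slot closer than this fraction of spacing to a line end
    n_total: int = 36


@dataclass
class ArcProfile:
    """Heatmap scores sampled at 1 px arc-length steps along a catheter line."""

    positions: np.ndarray  # arc length (px) from the line's top endpoint
    scores: np.ndarray
    rows: np.ndarray  # image point of each sample
    cols: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.scores) == len(self.rows) == len(self.cols)):
            raise ValueError("profile arrays must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def score_at(self, s: np.ndarray | float) -> np.ndarray:
        return np.interp(s, self.positions, self.scores)

    def point_at(self, s: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.interp(s, self.positions, self.rows),
            np.interp(s, self.positions, self.cols),
        )


def sensor_heatmap(image: np.ndarray, single_templates: list[Template]) -> np.ndarray:
    """NCC heatmap against the single-sensor templates (elementwise max)."""
    for t in single_templates:
        if t.kind != "single":
            raise ValueError("sensor_heatmap expects single-sensor templates")
    return ncc_heatmap(image, single_templates)


def profile_along_line(hm: np.ndarray, line: CatheterLine) -> ArcProfile:
    """Sample a heatmap (bilinearly) at 1 px arc steps along ``line``."""
    if len(line) == 0:
        raise ValueError("cannot profile an empty line")
    arc = line.arc()
    s = np.arange(0.0, np.floor(arc[-1]) + 1.0)
    rows = np.interp(s, arc, line.rows.astype(float))
    cols = np.interp(s, arc, line.cols)
    scores = map_coordinates(
        np.asarray(hm, dtype=float), np.vstack([rows, cols]), order=1, mode="nearest"
    )
    return ArcProfile(positions=s, scores=scores, rows=rows, cols=cols)


def detect_peaks(
    profile: ArcProfile, spacing_px: float, params: SensorParams | None = None
) -> np.ndarray:
    """Arc positions of sensor peaks under the minimum-separation constraint.

    Candidate peaks are local maxima scoring at least ``peak_floor``.  The
    emitted subset is the one maximizing total score subject to mutual
    separation >= ``min_sep_frac * spacing_px``, found exactly by dynamic
    programming over the (ordered) candidates; for well-separated sensors
    this reduces to plain non-maximum suppression.
    """
    if spacing_px <= 0:
        raise ValueError("spacing_px must be positive")
    if params is None:
        params = SensorParams()
    idx, _ = find_peaks(profile.scores, height=params.peak_floor)
    if len(idx) == 0:
        return np.zeros(0)
    pos = profile.positions[idx]
    score = profile.scores[idx]
    min_sep = params.min_sep_frac * spacing_px

    n = len(pos)
    best = np.zeros(n)  # best total score of a valid subset ending at i
    prev = np.full(n, -1, dtype=int)
    for i in range(n):
        best[i] = score[i]
        for j in range(i):
            if pos[i] - pos[j] >= min_sep and score[j] > 0 and best[j] + score[i] > best[i]:
                best[i] = best[j] + score[i]
                prev[i] = j
    chosen = []
    i = int(np.argmax(best))
    while i >= 0:
        chosen.append(i)
        i = prev[i]
    return pos[np.array(sorted(chosen))]


def _estimate_spacing(peaks: np.ndarray, spacing_px: float, tol_frac: float) -> float:
    if len(peaks) < 2:
        return spacing_px
    gaps = np.diff(peaks)
    # gaps near multiples of the spacing (missed sensors) are folded back
    mult = np.maximum(1, np.round(gaps / spacing_px))
    est = float(np.median(gaps / mult))
    return float(np.clip(est, (1 - tol_frac) * spacing_px, (1 + tol_frac) * spacing_px))


def regularize_and_number(
    peaks: np.ndarray,
    profile: ArcProfile,
    spacing_px: float,
    visible_end: str = "top",
    params: SensorParams | None = None,
) -> SensorSet:
    """Snap peaks to a regular arc grid, infer missing sensors, number them.

    Each peak is snapped to the nearest multiple of the locally estimated
    spacing (median inter-peak gap clipped to nominal +-20%).  Grid slots
    with no supporting peak get an *inferred* sensor at the interpolated
    (or, at the ends, extrapolated) arc position, as long as the slot stays
    a sensor-footprint margin inside the line span.  Numbering starts at
    the slot nearest the visible catheter end: index 1 at the top for
    ``visible_end='top'``, index ``n_total`` at the bottom for
    ``visible_end='bottom'``.  Fewer than three supporting peaks mark the
    frame ``low_confidence`` (numbering unreliable); sensors are still
    emitted.
    """
    if params is None:
        params = SensorParams()
    if visible_end not in ("top", "bottom"):
        raise ValueError("visible_end must be 'top' or 'bottom'")
    peaks = np.asarray(peaks, dtype=float)
    low_confidence = len(peaks) < 3
    if len(peaks) == 0:
        return SensorSet(sensors=[], low_confidence=True)

    s_est = _estimate_spacing(peaks, spacing_px, params.spacing_tol_frac)
    p0 = peaks[0]
    slot_of: dict[int, float] = {}
    for p in peaks:
        k = int(round((p - p0) / s_est))
        if k in slot_of:  # keep the stronger supporting peak
            if profile.score_at(p) > profile.score_at(slot_of[k]):
                slot_of[k] = p
        else:
            slot_of[k] = p

    known_k = np.array(sorted(slot_of))
    known_p = np.array([slot_of[k] for k in known_k])
    margin = params.margin_frac * s_est
    length = profile.length

    # extend the grid outward as long as an extrapolated sensor still fits
    k_lo = int(known_k[0])
    while known_p[0] - (known_k[0] - (k_lo - 1)) * s_est >= margin:
        k_lo -= 1
    k_hi = int(known_k[-1])
    while known_p[-1] + ((k_hi + 1) - known_k[-1]) * s_est <= length - margin:
        k_hi += 1

    entries: list[tuple[float, bool]] = []  # (arc position, inferred)
    for k in range(k_lo, k_hi + 1):
        if k in slot_of:
            entries.append((slot_of[k], False))
        elif k < known_k[0]:
            entries.append((known_p[0] - (known_k[0] - k) * s_est, True))
        elif k > known_k[-1]:
            entries.append((known_p[-1] + (k - known_k[-1]) * s_est, True))
        else:
            entries.append((float(np.interp(k, known_k, known_p)), True))

    m = len(entries)
    if visible_end == "top":
        numbers = list(range(1, m + 1))
    else:
        numbers = list(range(params.n_total - m + 1, params.n_total + 1))
    sensors: list[SensorDetection] = []
    for (arc_pos, inferred), num in zip(entries, numbers):
        if num < 1 or num > params.n_total:  # beyond the physical catheter
            continue
        r, c = profile.point_at(arc_pos)
        sensors.append(
            SensorDetection(
                index=num,
                row=float(r),
                col=float(c),
                arc=float(arc_pos),
                confidence=float(profile.score_at(arc_pos)),
                inferred=inferred,
            )
        )
    return SensorSet(sensors=sensors, low_confidence=low_confidence)
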