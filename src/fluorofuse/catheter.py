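"""Catheter-line detection with temporal error correction.

Stage one of the detector: a normalized-cross-correlation heatmap against
the three-sensor templates lights up along the catheter; the line is
extracted as the per-row heatmap argmax constrained to a mostly vertical,
slope-limited polyline.  Because contrast agent can wipe out the catheter
in individual frames, each frame's line is checked against the previous
three accepted lines and replaced by their average when it deviates too
much (or when detection fails outright); the corrected line then enters
the history, propagating the fix to subsequent frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import rotate
from skimage.feature import match_template

from .model import CatheterLine
from .templates import Template

SENTINEL = -1.0  # heatmap score where the template does not fully fit


class LineDetectionError(RuntimeError):
    """No admissible catheter line found in this frame."""


class SequenceStartError(RuntimeError):
    """Detection failed on the first frame: no history to fall back on."""


@dataclass
class CatheterParams:
    score_floor: float = 0.3  # minimum NCC score for a row to contribute
    max_slope_px: float = 3.0  # max column change per image row
    gap_max: int = 160  # rows; larger gaps break the line chain
    # sustained slope allowed across multi-row gaps (px/row); the full
    # max_slope_px applies only over slack_rows, so a long gap cannot
    # absorb a large sideways jump onto a parallel structure
    bridge_slope_px: float = 1.0
    slack_rows: int = 3
    min_span_frac: float = 0.5  # line must cover this fraction of image height
    # RMS column deviation from the history average that triggers a
    # correction; routine deviation (drift + bridging error) stays <= ~8 px
    dev_thresh_px: float = 15.0
    # in-plane rotations (deg) applied to the triple templates; a stack of
    # three sensors is long, so catheter tilt must be matched explicitly
    rotations: tuple = (-36.0, -24.0, -12.0, 0.0, 12.0, 24.0, 36.0)


def ncc_heatmap(
    image: np.ndarray,
    templates: list[Template],
    rotations: tuple = (0.0,),
) -> np.ndarray:
    """Elementwise-max NCC score map over ``templates`` (x ``rotations``).

    Scores are anchored at the template centers and live in [-1, 1];
    pixels where any template would overhang the image border carry the
    sentinel score -1.  Zero-variance windows (e.g. a constant image)
    score 0 by convention.  Non-zero ``rotations`` match rotated template
    variants, giving the long triple templates tolerance to catheter tilt.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    variants: list[np.ndarray] = []
    for t in templates:
        for ang in rotations:
            if ang == 0.0:
                variants.append(t.pixels)
            else:
                variants.append(
                    rotate(
                        t.pixels, ang, reshape=True, order=1, mode="constant", cval=0.5
                    )
                )
    for v in variants:
        if v.shape[0] >= img.shape[0] or v.shape[1] >= img.shape[1]:
            raise ValueError("image must be strictly larger than every template")
    out = np.full(img.shape, SENTINEL)
    for v in variants:
        th, tw = v.shape
        # pad_input=True indexes scores at the template center
        scores = match_template(img, v, pad_input=True)
        scores = np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)
        r0, r1 = th // 2, img.shape[0] - (th - th // 2 - 1)
        c0, c1 = tw // 2, img.shape[1] - (tw - tw // 2 - 1)
        region = out[r0:r1, c0:c1]
        np.maximum(region, scores[r0:r1, c0:c1], out=region)
    return np.clip(out, -1.0, 1.0)


def line_heatmap(
    image: np.ndarray,
    triple_templates: list[Template],
    rotations: tuple = CatheterParams.rotations,
) -> np.ndarray:
    """Stage-one heatmap: NCC against the three-sensor templates."""
    for t in triple_templates:
        if t.kind != "triple":
            raise ValueError("line_heatmap expects triple-sensor templates")
    return ncc_heatmap(image, triple_templates, rotations)


def extract_line(hm: np.ndarray, params: CatheterParams | None = None) -> CatheterLine:
    """Extract the catheter polyline from a triple-template heatmap.

    Per row, the candidate column is the score argmax; rows scoring below
    ``score_floor`` are dropped.  The longest chain of candidate rows whose
    column changes respect the slope bound (outlier candidates are skipped;
    row gaps up to ``gap_max`` are bridged by linear interpolation) becomes
    the line.  Raises :class:`LineDetectionError` when no chain covers
    ``min_span_frac`` of the image height.
    """
    if params is None:
        params = CatheterParams()
    hm = np.asarray(hm, dtype=float)
    n_rows = hm.shape[0]
    row_max = hm.max(axis=1)
    cand_rows = np.flatnonzero(row_max >= params.score_floor)
    if len(cand_rows) == 0:
        raise LineDetectionError("no heatmap row reaches the score floor")
    cand_cols = hm[cand_rows].argmax(axis=1).astype(float)
    cand_score = row_max[cand_rows]

    # best chain of mutually consistent candidates: i -> j admissible when
    # the row gap is bridgeable and the column change respects the slope
    # bound.  Chains are scored by accumulated margin above the floor, so a
    # short strong catheter segment beats a long chain of weak background
    # responses; outlier candidates are simply skipped, not chain-breaking.
    n = len(cand_rows)
    weight = cand_score - params.score_floor
    best = weight.copy()  # chain weight ending at i
    prev = np.full(n, -1, dtype=int)
    for i in range(n):
        lo = int(np.searchsorted(cand_rows, cand_rows[i] - params.gap_max))
        for j in range(lo, i):
            dr = cand_rows[i] - cand_rows[j]
            allowed = params.max_slope_px * min(dr, params.slack_rows) + params.bridge_slope_px * dr
            if abs(cand_cols[i] - cand_cols[j]) <= allowed:
                if best[j] + weight[i] > best[i]:
                    best[i] = best[j] + weight[i]
                    prev[i] = j
    end = int(np.argmax(best))
    chain = []
    while end >= 0:
        chain.append(end)
        end = prev[end]
    chain = chain[::-1]
    rows_seg = cand_rows[chain]
    cols_seg = cand_cols[chain]
    span = rows_seg[-1] - rows_seg[0] + 1
    if span < params.min_span_frac * n_rows:
        raise LineDetectionError(
            f"longest admissible chain spans {span} rows "
            f"(< {params.min_span_frac:.0%} of {n_rows})"
        )
    rows = np.arange(rows_seg[0], rows_seg[-1] + 1)
    cols = np.interp(rows, rows_seg, cols_seg)
    cols_idx = np.clip(np.round(cols).astype(int), 0, hm.shape[1] - 1)
    quality = float(hm[rows, cols_idx].mean())
    return CatheterLine(rows=rows, cols=cols, quality=quality)


def extend_full_height(
    line: CatheterLine, n_rows: int, fit_rows: int = 25, max_slope_px: float = 3.0
) -> CatheterLine:
    """Linearly extrapolate a line to cover rows 0..n_rows-1.

    The heatmap carries sentinel scores in the template-border margin, so
    a detected line never quite reaches the frame edges even though the
    catheter does.  Each end is extended with the least-squares slope of
    its nearest ``fit_rows`` rows (clamped to ``max_slope_px``), letting
    the sensor stage infer sensors in the margins.
    """
    rows = line.rows
    cols = line.cols
    if rows[0] > 0:
        k = min(fit_rows, len(rows))
        slope = np.polyfit(rows[:k], cols[:k], 1)[0] if k > 1 else 0.0
        slope = float(np.clip(slope, -max_slope_px, max_slope_px))
        new_rows = np.arange(0, rows[0])
        new_cols = cols[0] + slope * (new_rows - rows[0])
        rows = np.concatenate([new_rows, rows])
        cols = np.concatenate([new_cols, cols])
    if rows[-1] < n_rows - 1:
        k = min(fit_rows, len(line.rows))
        slope = (
            np.polyfit(line.rows[-k:], line.cols[-k:], 1)[0] if k > 1 else 0.0
        )
        slope = float(np.clip(slope, -max_slope_px, max_slope_px))
        new_rows = np.arange(rows[-1] + 1, n_rows)
        new_cols = cols[-1] + slope * (new_rows - rows[-1])
        rows = np.concatenate([rows, new_rows])
        cols = np.concatenate([cols, new_cols])
    return CatheterLine(rows=rows, cols=cols, quality=line.quality)


@dataclass
class LineHistory:
    """The last (up to) three accepted catheter lines with frame indices."""

    window: int = 3
    entries: list[tuple[int, CatheterLine]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def push(self, frame_idx: int, line: CatheterLine) -> None:
        if self.entries and frame_idx <= self.entries[-1][0]:
            raise ValueError("frame indices must be increasing")
        self.entries.append((frame_idx, line))
        del self.entries[: -self.window]

    def average(self) -> CatheterLine:
        """Per-row mean of the stored lines over the union of their spans."""
        if not self.entries:
            raise ValueError("history is empty")
        lines = [ln for _, ln in self.entries]
        r0 = min(ln.rows[0] for ln in lines)
        r1 = max(ln.rows[-1] for ln in lines)
        rows = np.arange(r0, r1 + 1)
        total = np.zeros(len(rows))
        count = np.zeros(len(rows))
        for ln in lines:
            lo, hi = ln.rows[0] - r0, ln.rows[-1] - r0 + 1
            total[lo:hi] += ln.cols
            count[lo:hi] += 1
        covered = count > 0
        cols = np.empty(len(rows))
        cols[covered] = total[covered] / count[covered]
        if not covered.all():  # bridge rows no stored line covers
            cols[~covered] = np.interp(rows[~covered], rows[covered], cols[covered])
        quality = float(np.mean([ln.quality for ln in lines if ln.quality is not None] or [0.0]))
        return CatheterLine(rows=rows, cols=cols, quality=quality)


def temporal_correct(
    current: CatheterLine | None,
    hist: LineHistory,
    frame_idx: int,
    dev_thresh_px: float = 25.0,
) -> tuple[CatheterLine, bool]:
    """Accept, or correct from history, the current frame's line.

    ``current=None`` signals a failed detection.  With an empty history the
    current line is accepted as-is (or :class:`SequenceStartError` raised
    on failure).  Otherwise the root-mean-square per-row column deviation
    between the current line and the history average (over overlapping
    rows) decides: above ``dev_thresh_px``, or on failure, the history
    average replaces the detection.  The quadratic mean is used so that a
    gross deviation confined to one stretch of the line (the typical
    bolus-occlusion failure) is not diluted by agreement elsewhere.  The
    accepted line is pushed into the history, so a correction propagates
    to subsequent frames.  Returns ``(accepted_line, corrected_flag)``.
    """
    if len(hist) == 0:
        if current is None:
            raise SequenceStartError(
                "catheter detection failed on the first frame; no history to fall back on"
            )
        hist.push(frame_idx, current)
        return current, False

    avg = hist.average()
    corrected = False
    if current is None:
        accepted = avg
        corrected = True
    else:
        lo = max(current.rows[0], avg.rows[0])
        hi = min(current.rows[-1], avg.rows[-1])
        if hi < lo:
            deviation = np.inf
        else:
            rows = np.arange(lo, hi + 1)
            deviation = float(
                np.sqrt(np.mean((current.col_at_row(rows) - avg.col_at_row(rows)) ** 2))
            )
        if deviation > dev_thresh_px:
            accepted = avg
            corrected = True
        else:
            accepted = current
    hist.push(frame_idx, accepted)
    return accepted, corrected
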