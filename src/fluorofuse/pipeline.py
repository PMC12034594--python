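"""End-to-end detection pipeline: preprocess -> line -> sensors (-> overlay).

`detect_sequence` is the library entry point used by the CLI, the noise
study, and the acceptance checks; it is deterministic given its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .catheter import (
    CatheterParams,
    LineDetectionError,
    LineHistory,
    extend_full_height,
    extract_line,
    line_heatmap,
    temporal_correct,
)
from .model import CatheterLine, FrameSequence, SensorSet
from .phantom import PhantomSpec
from .preprocess import PreprocessParams, crop_borders, enhance
from .sensors import (
    SensorParams,
    detect_peaks,
    profile_along_line,
    regularize_and_number,
    sensor_heatmap,
)
from .templates import Template, bank_for_geometry, singles, triples

log = logging.getLogger("fluorofuse")


@dataclass
class DetectorParams:
    """Everything the detector needs besides the frames themselves."""

    spacing_px: float = 38.0
    sensor_len_px: float = 27.0
    sensor_width_px: float = 10.0
    visible_end: str = "top"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    catheter: CatheterParams = field(default_factory=CatheterParams)
    sensor: SensorParams = field(default_factory=SensorParams)

    @classmethod
    def for_phantom(cls, spec: PhantomSpec) -> "DetectorParams":
        """Detector configured with the phantom's nominal geometry."""
        return cls(
            spacing_px=spec.spacing_px,
            sensor_len_px=spec.sensor_len_px,
            sensor_width_px=spec.sensor_width_px,
            visible_end=spec.visible_end,
        )

    def bank(self) -> list[Template]:
        return bank_for_geometry(self.sensor_len_px, self.sensor_width_px, self.spacing_px)


@dataclass
class DetectionResult:
    lines: list[CatheterLine]  # accepted, full-height, original frame coords
    sensor_sets: list[SensorSet]
    corrected_frames: list[int]  # frames where temporal correction overrode detection


def detect_sequence(
    frames: np.ndarray | FrameSequence, params: DetectorParams | None = None
) -> DetectionResult:
    """Run the full two-stage detector over a frame stack.

    Per frame: crop uniform borders, Gaussian blur + CLAHE, triple-template
    heatmap -> catheter line (with the three-frame temporal correction),
    extend the accepted line to full height, single-template heatmap ->
    sensor peaks -> regularized, numbered sensor set.  Coordinates are
    reported in the original (uncropped) frame system.
    """
    if params is None:
        params = DetectorParams()
    stack = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    if stack.ndim != 3:
        raise ValueError("expected a (n_frames, rows, cols) stack")

    bank = params.bank()
    bank_triples, bank_singles = triples(bank), singles(bank)
    hist = LineHistory()
    lines: list[CatheterLine] = []
    sensor_sets: list[SensorSet] = []
    corrected_frames: list[int] = []

    for i, frame in enumerate(stack):
        try:
            cropped, (r_off, c_off) = crop_borders(
                frame, params.preprocess.border_uniformity_tol
            )
            enhanced = enhance(cropped, params.preprocess)

            hm_line = line_heatmap(enhanced, bank_triples, params.catheter.rotations)
            try:
                line = extract_line(hm_line, params.catheter)
            except LineDetectionError:
                line = None
            accepted, corrected = temporal_correct(
                line, hist, i, params.catheter.dev_thresh_px
            )
            if corrected:
                corrected_frames.append(i)
                log.info("frame %d: catheter line corrected from history", i)
            full_line = extend_full_height(
                accepted, cropped.shape[0], max_slope_px=params.catheter.max_slope_px
            )

            hm_sensor = sensor_heatmap(enhanced, bank_singles)
            profile = profile_along_line(hm_sensor, full_line)
            peaks = detect_peaks(profile, params.spacing_px, params.sensor)
            sset = regularize_and_number(
                peaks, profile, params.spacing_px, params.visible_end, params.sensor
            )
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc

        # back to original (uncropped) coordinates
        out_line = CatheterLine(
            rows=full_line.rows + r_off,
            cols=full_line.cols + c_off,
            quality=full_line.quality,
        )
        for s in sset:
            s.row += r_off
            s.col += c_off
        lines.append(out_line)
        sensor_sets.append(sset)
    return DetectionResult(lines=lines, sensor_sets=sensor_sets, corrected_frames=corrected_frames)
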