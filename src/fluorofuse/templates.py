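"""Synthetic matching templates for the two detection stages.

Stage one (catheter-line detection) matches two templates showing three
stacked sensors each; stage two (single-sensor localization) matches two
templates showing one sensor each.  Each stage uses a larger and a
smaller sensor geometry for robustness against patient-to-patient
variation in apparent sensor size.  Templates are generated
programmatically with the same soft-bar profile the phantom renders, so
the bank stays geometry-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .draw import stamp_bar

BACKGROUND = 0.5
BAR_DEPTH = 0.35


@dataclass(frozen=True)
class TemplateGeometry:
    """Sensor geometry (px) a template is built from."""

    sensor_len_px: float
    sensor_width_px: float
    spacing_px: float

    def scaled(self, factor: float) -> "TemplateGeometry":
        return TemplateGeometry(
            self.sensor_len_px * factor,
            self.sensor_width_px * factor,
            self.spacing_px * factor,
        )


#: Default presets at the native 1024x1024 scale.
LARGE = TemplateGeometry(sensor_len_px=30, sensor_width_px=12, spacing_px=38)
SMALL = TemplateGeometry(sensor_len_px=24, sensor_width_px=9, spacing_px=38)


@dataclass
class Template:
    pixels: np.ndarray  # small float image in [0, 1]
    kind: str  # "triple" | "single"
    scale: str  # "large" | "small"
    anchor: tuple[int, int]  # (row, col) offset of the reference sensor center

    def __post_init__(self) -> None:
        h, w = self.pixels.shape
        ar, ac = self.anchor
        if not (0 <= ar < h and 0 <= ac < w):
            raise ValueError("anchor must lie inside the template bounds")


def _odd(x: float) -> int:
    n = int(np.ceil(x))
    return n if n % 2 == 1 else n + 1


def _blank(height: float, width: float) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = _odd(height), _odd(width)
    img = np.full((h, w), BACKGROUND)
    return img, (h // 2, w // 2)


def make_single_template(
    sensor_len_px: float, sensor_width_px: float, scale: str = "large"
) -> Template:
    """One vertically oriented dark sensor bar, anchored at its center."""
    if sensor_len_px <= 0 or sensor_width_px <= 0:
        raise ValueError("sensor dimensions must be positive")
    img, center = _blank(sensor_len_px * 1.8, sensor_width_px * 3.0)
    stamp_bar(img, center, (1.0, 0.0), sensor_len_px, sensor_width_px, BAR_DEPTH)
    return Template(pixels=img, kind="single", scale=scale, anchor=center)


def make_triple_template(
    sensor_len_px: float,
    spacing_px: float,
    sensor_width_px: float,
    scale: str = "large",
) -> Template:
    """Three stacked sensor bars at the nominal spacing, anchored at the middle bar."""
    if sensor_len_px <= 0 or sensor_width_px <= 0 or spacing_px <= 0:
        raise ValueError("geometry dimensions must be positive")
    if spacing_px <= sensor_len_px:
        raise ValueError("spacing_px must exceed sensor_len_px: bars would overlap")
    img, center = _blank(2 * spacing_px + sensor_len_px * 1.6, sensor_width_px * 3.0)
    for offset in (-spacing_px, 0.0, spacing_px):
        stamp_bar(
            img,
            (center[0] + offset, center[1]),
            (1.0, 0.0),
            sensor_len_px,
            sensor_width_px,
            BAR_DEPTH,
        )
    return Template(pixels=img, kind="triple", scale=scale, anchor=center)


def template_bank(
    large: TemplateGeometry = LARGE, small: TemplateGeometry = SMALL
) -> list[Template]:
    """The four templates used by the pipeline: {triple, single} x {large, small}."""
    if large.sensor_len_px <= small.sensor_len_px:
        raise ValueError("'large' preset must have the longer sensor")
    out = []
    for scale, g in (("large", large), ("small", small)):
        out.append(
            make_triple_template(g.sensor_len_px, g.spacing_px, g.sensor_width_px, scale)
        )
        out.append(make_single_template(g.sensor_len_px, g.sensor_width_px, scale))
    return out


def bank_for_geometry(
    sensor_len_px: float, sensor_width_px: float, spacing_px: float
) -> list[Template]:
    """Bank derived from a nominal sensor geometry.

    The large/small presets bracket the nominal sensor size by +-1/9 (the
    ratio between the default presets and a nominal 27 px sensor); the
    inter-sensor spacing is a property of the catheter and is not scaled.
    """
    large = TemplateGeometry(
        sensor_len_px * 10.0 / 9.0, sensor_width_px * 10.0 / 9.0, spacing_px
    )
    small = TemplateGeometry(
        sensor_len_px * 8.0 / 9.0, sensor_width_px * 8.0 / 9.0, spacing_px
    )
    return template_bank(large=large, small=small)


def triples(bank: list[Template]) -> list[Template]:
    return [t for t in bank if t.kind == "triple"]


def singles(bank: list[Template]) -> list[Template]:
    return [t for t in bank if t.kind == "single"]
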