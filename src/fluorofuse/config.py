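"""Run configuration: one YAML file covering the whole parameter surface.

The parameter surface is large (preprocess, templates, catheter, sensor,
fusion, evaluation), so runs are driven by a structured config file with
flag overrides rather than dozens of CLI flags.  ``load`` / ``save``
round-trip exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .catheter import CatheterParams
from .pipeline import DetectorParams
from .preprocess import PreprocessParams
from .sensors import SensorParams


@dataclass
class FusionConfig:
    mano_min: float = -10.0
    mano_max: float = 150.0
    imped_min: float = 50.0
    imped_max: float = 2000.0
    imped_log: bool = True
    ribbon_width: float = 8.0
    imped_offset: float = 14.0


@dataclass
class RunConfig:
    """Paths plus every tunable section of the pipeline."""

    frames: str = ""  # directory of PNGs or a multi-page TIFF
    physio: str = ""  # wide physiology CSV ('' = none)
    truth: str = ""  # ground-truth CSV ('' = none)
    out_dir: str = "out"
    fps: float = 10.0
    visible_end: str = "top"
    seed: int = 0
    spacing_px: float = 38.0
    sensor_len_px: float = 27.0
    sensor_width_px: float = 10.0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    catheter: CatheterParams = field(default_factory=CatheterParams)
    sensor: SensorParams = field(default_factory=SensorParams)
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def detector_params(self) -> DetectorParams:
        return DetectorParams(
            spacing_px=self.spacing_px,
            sensor_len_px=self.sensor_len_px,
            sensor_width_px=self.sensor_width_px,
            visible_end=self.visible_end,
            preprocess=self.preprocess,
            catheter=self.catheter,
            sensor=self.sensor,
        )

    def save(self, path: str | Path) -> None:
        data = asdict(self)
        data["preprocess"]["clahe_tile_grid"] = list(
            data["preprocess"]["clahe_tile_grid"]
        )
        data["catheter"]["rotations"] = list(data["catheter"]["rotations"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "preprocess" in kwargs:
            pp = dict(kwargs["preprocess"])
            if "clahe_tile_grid" in pp:
                pp["clahe_tile_grid"] = tuple(pp["clahe_tile_grid"])
            kwargs["preprocess"] = PreprocessParams(**pp)
        if "catheter" in kwargs:
            cp = dict(kwargs["catheter"])
            if "rotations" in cp:
                cp["rotations"] = tuple(cp["rotations"])
            kwargs["catheter"] = CatheterParams(**cp)
        if "sensor" in kwargs:
            kwargs["sensor"] = SensorParams(**kwargs["sensor"])
        if "fusion" in kwargs:
            kwargs["fusion"] = FusionConfig(**kwargs["fusion"])
        return cls(**kwargs)
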