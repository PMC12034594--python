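"""Synthetic fluoroscopy phantom with exact sensor ground truth.

Emulates the acquisition geometry of an esophageal high-resolution
manometry examination imaged with low-dose videofluoroscopy: a smoothly
curved, mostly vertical catheter carrying 36 sensors 1 cm apart (35-40 px
at the native 1024x1024 resolution), of which roughly 30 are inside the
field of view; a radiopaque bolus that can occlude sensors; smooth
background intensity gradients standing in for anatomy and windowing; and
additive Gaussian image noise at four named levels.  Synchronized
manometry and impedance traces carry a single propagating contraction
wave, the basic structure seen in Clouse plots.

Everything is a deterministic function of the :class:`PhantomSpec`
(including its seed), so detection stages can be tested against exact
ground truth without clinical data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .draw import stamp_bar
from .model import (
    CatheterLine,
    FrameSequence,
    GroundTruth,
    PhysioRecord,
    TruthSensor,
    N_IMPEDANCE_CHANNELS,
    N_MANO_CHANNELS,
    PHYSIO_RATE_HZ,
)

#: Named Gaussian noise levels -> sigma on the 8-bit intensity scale.
NOISE_LEVELS = {"none": 0.0, "little": 10.0, "medium": 25.0, "most": 50.0}

SENSOR_DEPTH = 90.0  # intensity decrement of a sensor blob (8-bit scale)
# the contrast-agent bolus is effectively fully radiopaque: deep enough to
# saturate the image to black, wiping out local contrast (and the sensors)
BOLUS_DEPTH = 200.0
# a sensor counts as occluded when its whole bar (center and both ends)
# lies inside the bolus footprint; a bar tip poking past the rim leaves
# the sensor partially visible, which is not occlusion
OCCLUSION_THRESHOLD = 0.5


class PhantomGeometryError(ValueError):
    """The requested geometry cannot fit a single sensor in the frame."""


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition.

    Defaults are the half-scale (512x512) version of the native acquisition
    geometry (1024x1024, sensor spacing 35-40 px, sensor length 25-30 px);
    use :meth:`full_scale` for the native resolution.
    """

    image_size: tuple[int, int] = (512, 512)
    n_frames: int = 40
    fps: float = 10.0  # frames/s, within the clinical 8-15 range
    n_sensors_total: int = 36
    n_visible: int = 30  # upper bound; as many as fit are rendered
    spacing_px: float = 19.0
    sensor_len_px: float = 13.0
    sensor_width_px: float = 5.0
    visible_end: str = "top"  # which catheter end is inside the frame
    curve_amplitude_px: float = 40.0
    drift_px: float = 6.0  # slow anatomical drift amplitude across frames
    bolus_enabled: bool = False
    bolus_speed_px_per_frame: float = 6.0
    bolus_start_frac: float = 0.0  # bolus arc position at frame 0, fraction of path
    bolus_len_px: float | None = None  # default 5.5 * spacing
    bolus_width_px: float | None = None  # default 2.5 * spacing
    noise_level: str = "none"  # one of NOISE_LEVELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_px <= self.sensor_len_px:
            raise ValueError("spacing_px must exceed sensor_len_px (no sensor overlap)")
        if not (8.0 <= self.fps <= 15.0):
            raise ValueError("fps must lie in the clinical range [8, 15]")
        if self.n_visible > self.n_sensors_total:
            raise ValueError("n_visible cannot exceed n_sensors_total")
        if self.visible_end not in ("top", "bottom"):
            raise ValueError("visible_end must be 'top' or 'bottom'")
        if self.noise_level not in NOISE_LEVELS:
            raise ValueError(f"noise_level must be one of {sorted(NOISE_LEVELS)}")

    @property
    def noise_sigma(self) -> float:
        return NOISE_LEVELS[self.noise_level]

    @property
    def bolus_length(self) -> float:
        return self.bolus_len_px if self.bolus_len_px is not None else 5.5 * self.spacing_px

    @property
    def bolus_width(self) -> float:
        return self.bolus_width_px if self.bolus_width_px is not None else 2.5 * self.spacing_px

    @classmethod
    def full_scale(cls, **overrides) -> "PhantomSpec":
        """The native 1024x1024 acquisition geometry."""
        base = dict(
            image_size=(1024, 1024),
            spacing_px=38.0,
            sensor_len_px=27.0,
            sensor_width_px=10.0,
            curve_amplitude_px=80.0,
            drift_px=12.0,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "PhantomSpec":
        return dataclasses.replace(self, **changes)


def _curve_params(spec: PhantomSpec) -> dict:
    """Per-dataset catheter shape parameters, fixed by the spec seed."""
    rng = np.random.default_rng([spec.seed, 11])
    rows, cols = spec.image_size
    return {
        "center_col": cols / 2.0 + rng.uniform(-0.06, 0.06) * cols,
        "freq1": rng.uniform(0.7, 1.3),
        "phase1": rng.uniform(0.0, 2.0 * np.pi),
        "freq2": rng.uniform(1.8, 2.6),
        "phase2": rng.uniform(0.0, 2.0 * np.pi),
        "drift_phase": rng.uniform(0.0, 2.0 * np.pi),
        # period chosen so per-frame drift never exceeds ~1 px
        "drift_period": max(40.0, spec.drift_px * 2.0 * np.pi / 1.0),
    }


def generate_catheter_path(spec: PhantomSpec, frame_idx: int) -> CatheterLine:
    """Smooth, mostly vertical catheter polyline for one frame.

    The shape is a two-harmonic sinusoid in the row coordinate whose maximum
    horizontal excursion is bounded by ``curve_amplitude_px``; the whole
    curve drifts slowly sideways across frames (<= 3 px frame-to-frame).
    Deterministic given (spec.seed, frame_idx).
    """
    if frame_idx >= spec.n_frames:
        raise ValueError("frame_idx must be < n_frames")
    p = _curve_params(spec)
    rows, cols = spec.image_size
    r = np.arange(rows)
    t = r / max(rows - 1, 1)
    shape = np.sin(2 * np.pi * p["freq1"] * t + p["phase1"])
    shape = shape + 0.35 * np.sin(2 * np.pi * p["freq2"] * t + p["phase2"])
    peak = np.max(np.abs(shape))
    if peak > 0 and spec.curve_amplitude_px > 0:
        shape = shape / peak * spec.curve_amplitude_px
    else:
        shape = np.zeros_like(shape)
    drift = spec.drift_px * np.sin(
        2 * np.pi * frame_idx / p["drift_period"] + p["drift_phase"]
    )
    margin = spec.sensor_width_px + 4.0
    c = np.clip(p["center_col"] + drift + shape, margin, cols - 1 - margin)
    return CatheterLine(rows=r, cols=c, quality=None)


def _sensor_arcs(spec: PhantomSpec, path: CatheterLine) -> list[tuple[int, float]]:
    """(sensor_index, arc_position) for every sensor that fits in the frame.

    Sensors sit at multiples of ``spacing_px`` of arc length starting half a
    spacing in from the visible catheter end; a sensor is rendered when its
    full footprint fits on the path.  Index 1 is the proximal (top) hardware
    end: with ``visible_end='top'`` the visible sensors are 1..k counted
    downward, with ``visible_end='bottom'`` they are (37-k)..36 with sensor
    ``n_sensors_total`` lowest in the frame.
    """
    L = path.length
    half = spec.sensor_len_px / 2.0
    s0 = 0.5 * spec.spacing_px
    out: list[tuple[int, float]] = []
    for k in range(spec.n_visible):
        if spec.visible_end == "top":
            arc = s0 + k * spec.spacing_px
            idx = 1 + k
        else:
            arc = L - s0 - k * spec.spacing_px
            idx = spec.n_sensors_total - k
        if arc < half or arc > L - half:
            break
        out.append((idx, arc))
    if not out:
        raise PhantomGeometryError(
            "frame cannot fit a single sensor with the requested geometry"
        )
    return sorted(out, key=lambda t: t[1])


def _background(spec: PhantomSpec, frame_idx: int) -> np.ndarray:
    """Smooth anatomy-like intensity background, deterministic per spec."""
    rng = np.random.default_rng([spec.seed, 23])
    rows, cols = spec.image_size
    yy, xx = np.meshgrid(
        np.linspace(0, 1, rows), np.linspace(0, 1, cols), indexing="ij"
    )
    ph = rng.uniform(0, 2 * np.pi, size=4)
    img = (
        150.0
        + 18.0 * np.sin(2 * np.pi * (0.8 * xx) + ph[0])
        + 12.0 * np.sin(2 * np.pi * (0.6 * yy) + ph[1])
        + 8.0 * np.sin(2 * np.pi * (1.3 * xx + 0.9 * yy) + ph[2])
    )
    # mild vignette and a slow exposure flicker over time
    rr2 = (yy - 0.5) ** 2 + (xx - 0.5) ** 2
    img -= 20.0 * rr2
    img += 3.0 * np.sin(2 * np.pi * frame_idx / 30.0 + ph[3])
    return img


def _bolus_arc(spec: PhantomSpec, path: CatheterLine, frame_idx: int) -> float:
    s = spec.bolus_start_frac * path.length + spec.bolus_speed_px_per_frame * frame_idx
    return float(np.clip(s, 0.0, path.length))


def render_frame(
    spec: PhantomSpec,
    path: CatheterLine,
    frame_idx: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[TruthSensor]]:
    """Render one frame and its exact ground-truth sensor list.

    Geometry (background, catheter, sensors, bolus) is deterministic given
    the spec; ``rng`` is consumed only for the additive Gaussian noise, so
    the ground truth is identical across noise levels.
    """
    img = _background(spec, frame_idx)
    sensors = _sensor_arcs(spec, path)

    arc = path.arc()
    # local tangents for orienting the sensor bars
    tan_r = np.gradient(path.rows.astype(float))
    tan_c = np.gradient(path.cols)
    norm = np.hypot(tan_r, tan_c)
    tan_r, tan_c = tan_r / norm, tan_c / norm

    # faint catheter shaft connecting the sensors
    shaft_cols = np.round(path.cols).astype(int)
    img[path.rows, shaft_cols] -= 10.0
    img[path.rows, np.clip(shaft_cols + 1, 0, img.shape[1] - 1)] -= 6.0

    bolus_footprint = None
    if spec.bolus_enabled:
        s_b = _bolus_arc(spec, path, frame_idx)
        br, bc = path.point_at_arc(s_b)
        i_b = int(np.clip(np.searchsorted(arc, s_b), 0, len(arc) - 1))
        # barium boluses image with sharp boundaries: a narrow edge keeps the
        # partially-visible rim band only a couple of pixels wide
        bolus_footprint = stamp_bar(
            img,
            (float(br), float(bc)),
            (float(tan_r[i_b]), float(tan_c[i_b])),
            spec.bolus_length,
            spec.bolus_width,
            BOLUS_DEPTH,
            edge=2.0,
        )

    truth: list[TruthSensor] = []
    for idx, s in sensors:
        r, c = path.point_at_arc(s)
        i_t = int(np.clip(np.searchsorted(arc, s), 0, len(arc) - 1))
        stamp_bar(
            img,
            (float(r), float(c)),
            (float(tan_r[i_t]), float(tan_c[i_t])),
            spec.sensor_len_px,
            spec.sensor_width_px,
            SENSOR_DEPTH,
        )
        occluded = False
        if bolus_footprint is not None:
            half = spec.sensor_len_px / 2.0
            probes = []
            for ds in (-half, 0.0, half):
                pr, pc = path.point_at_arc(s + ds)
                rr = int(np.clip(round(float(pr)), 0, img.shape[0] - 1))
                cc = int(np.clip(round(float(pc)), 0, img.shape[1] - 1))
                probes.append(bolus_footprint[rr, cc])
            occluded = min(probes) >= OCCLUSION_THRESHOLD
        truth.append(TruthSensor(index=idx, row=float(r), col=float(c), occluded=occluded))

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).round().astype(np.uint8)
    return img, truth


def generate_physio(spec: PhantomSpec, rng: np.random.Generator) -> PhysioRecord:
    """Synchronized manometry/impedance traces with a propagating wave.

    Manometry: per-channel resting baseline plus one Gaussian-profile
    pressure wave traveling from channel 1 to 36 over the sequence
    duration (peristaltic contraction).  Impedance: high baseline with a
    transient drop co-propagating with the wave (bolus presence lowers
    impedance).  Sampled at 50 Hz, sharing the frame-sequence time origin.
    """
    duration = spec.n_frames / spec.fps
    n = int(round(duration * PHYSIO_RATE_HZ))
    t = np.arange(n) / PHYSIO_RATE_HZ

    def wave_time(channel_pos: float) -> float:
        # channel_pos in [1, 36]; wave occupies the central 80% of the record
        return duration * (0.1 + 0.8 * (channel_pos - 1.0) / (N_MANO_CHANNELS - 1.0))

    sigma_w = max(0.12, 0.04 * duration)
    baselines = 5.0 + rng.normal(0.0, 1.5, size=N_MANO_CHANNELS)
    mano = np.empty((N_MANO_CHANNELS, n))
    for k in range(N_MANO_CHANNELS):
        tau = wave_time(k + 1.0)
        mano[k] = baselines[k] + 120.0 * np.exp(-((t - tau) ** 2) / (2 * sigma_w**2))

    sigma_b = 2.5 * sigma_w
    imp_base = 1800.0 + rng.normal(0.0, 40.0, size=N_IMPEDANCE_CHANNELS)
    imped = np.empty((N_IMPEDANCE_CHANNELS, n))
    for k in range(N_IMPEDANCE_CHANNELS):
        mid_sensor = 3.0 + 2.0 * (k + 1)  # midpoint of the channel's sensor pair
        tau = wave_time(mid_sensor)
        imped[k] = imp_base[k] - 1500.0 * np.exp(-((t - tau) ** 2) / (2 * sigma_b**2))

    return PhysioRecord(mano=mano, imped=imped, rate=PHYSIO_RATE_HZ, t0=0.0)


def generate_dataset(
    spec: PhantomSpec,
) -> tuple[FrameSequence, GroundTruth, PhysioRecord]:
    """Render the full phantom acquisition: frames, truth, physio.

    Deterministic: the same spec (including seed) yields bit-identical
    output.  Frames, ground truth, and physiology share the time origin
    t=0 at frame 0.
    """
    frames = []
    per_frame: list[list[TruthSensor]] = []
    for i in range(spec.n_frames):
        path = generate_catheter_path(spec, i)
        noise_rng = np.random.default_rng([spec.seed, 7, i])
        img, truth = render_frame(spec, path, i, noise_rng)
        frames.append(img)
        per_frame.append(truth)
    seq = FrameSequence(
        frames=np.stack(frames),
        fps=spec.fps,
        timestamps=np.arange(spec.n_frames) / spec.fps,
    )
    physio = generate_physio(spec, np.random.default_rng([spec.seed, 99]))
    return seq, GroundTruth(per_frame=per_frame), physio


def add_noise(frames: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise applied to already-rendered (acquired) frames."""
    if sigma <= 0:
        return frames.copy()
    noisy = frames.astype(float) + rng.normal(0.0, sigma, size=frames.shape)
    return np.clip(noisy, 0, 255).round().astype(np.uint8)
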