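"""Canonical phantom benchmark studies for the detection pipeline.

These reproduce, on synthetic data with exact ground truth, the style of
evaluation used for the clinical system: precision/recall/F1 at the three
accuracy radii, robustness across the four Gaussian-noise levels, and
recovery of bolus-occluded sensors.  The studies are deterministic given
their seeds and are shared by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import (
    AccuracyLevels,
    EvalReport,
    evaluate_sequence,
    match_frame,
    noise_study,
    score,
)
from .model import GroundTruth
from .phantom import PhantomSpec, generate_catheter_path, generate_dataset
from .pipeline import DetectorParams, detect_sequence


def clean_study(
    seed: int = 0, n_sequences: int = 5, n_frames: int = 40
) -> EvalReport:
    """Detection on clean phantoms: no bolus, noise level "none".

    Runs the full pipeline on ``n_sequences`` seeded 512x512 sequences and
    pools per-sequence P/R/F1 at the three accuracy radii.
    """
    reports = []
    for s in range(n_sequences):
        spec = PhantomSpec(seed=seed + s, n_frames=n_frames)
        frames, truth, _ = generate_dataset(spec)
        res = detect_sequence(frames.frames, DetectorParams.for_phantom(spec))
        reports.append(evaluate_sequence(res.sensor_sets, truth))
    return score(reports)


def robustness_study(
    seed: int = 0, n_sequences: int = 3, n_frames: int = 15
) -> dict[str, EvalReport]:
    """F1 across the four named Gaussian-noise levels (added post-render)."""
    spec = PhantomSpec(seed=seed, n_frames=n_frames)
    params = DetectorParams.for_phantom(spec)
    return noise_study(
        spec,
        lambda stack: detect_sequence(stack, params).sensor_sets,
        n_sequences=n_sequences,
    )


@dataclass
class OcclusionReport:
    """Outcome of the bolus-occlusion recovery study."""

    n_occluded_frames: int  # frames with >= 5 occluded sensors
    max_consecutive_occluded_frames: int
    line_rms_px: float  # worst-case line RMS error over occluded frames
    n_occluded_sensors: int
    recovered_inferred_within_30px: int

    @property
    def recovery_rate(self) -> float:
        return self.recovered_inferred_within_30px / max(self.n_occluded_sensors, 1)


def occlusion_study(seed: int = 7, n_frames: int = 30) -> OcclusionReport:
    """A radiopaque bolus sweeps down the catheter, hiding sensors.

    Measures (a) the worst-case RMS deviation of the temporally corrected
    catheter line from the true path over frames with >= 5 occluded
    sensors, and (b) how many occluded sensors are recovered as inferred
    detections within 30 px of their true position (one-to-one matched).
    """
    spec = PhantomSpec(
        seed=seed,
        n_frames=n_frames,
        bolus_enabled=True,
        bolus_speed_px_per_frame=8.0,
        bolus_start_frac=0.25,  # below the numbering anchor, mid-band sweep
        bolus_len_px=None,
    )
    spec = spec.replace(bolus_len_px=6.0 * spec.spacing_px)
    frames, truth, _ = generate_dataset(spec)
    res = detect_sequence(frames.frames, DetectorParams.for_phantom(spec))

    heavy = [i for i in range(n_frames) if sum(t.occluded for t in truth.frame(i)) >= 5]
    streak = best = 0
    for i in range(n_frames):
        streak = streak + 1 if i in heavy else 0
        best = max(best, streak)

    worst_rms = 0.0
    for i in heavy:
        path = generate_catheter_path(spec, i)
        line = res.lines[i]
        err = line.cols - path.cols[line.rows]
        worst_rms = max(worst_rms, float(np.sqrt(np.mean(err**2))))

    tot = ok = 0
    for i in range(n_frames):
        occ = [t for t in truth.frame(i) if t.occluded]
        if not occ:
            continue
        inferred_pts = np.array(
            [[d.row, d.col] for d in res.sensor_sets[i] if d.inferred]
        ).reshape(-1, 2)
        m = match_frame(inferred_pts, occ, AccuracyLevels().acceptable_px)
        tot += len(occ)
        ok += m.n_tp

    return OcclusionReport(
        n_occluded_frames=len(heavy),
        max_consecutive_occluded_frames=best,
        line_rms_px=worst_rms,
        n_occluded_sensors=tot,
        recovered_inferred_within_30px=ok,
    )


def matcher_oracle_study(seed: int = 0, n_instances: int = 200) -> dict:
    """Evaluation matcher vs exhaustive enumeration on small instances.

    Random instances with up to 6 detections/truth points each; returns
    the number of instances where the matcher's one-to-one TP count
    equals the brute-force maximum bipartite TP count.
    """
    import itertools

    def optimal_tp(det, tru, radius):
        ok = [
            [float(np.hypot(*(d - t))) <= radius for t in tru] for d in det
        ]
        for k in range(min(len(det), len(tru)), 0, -1):
            for di in itertools.permutations(range(len(det)), k):
                for tj in itertools.combinations(range(len(tru)), k):
                    if all(ok[i][j] for i, j in zip(di, tj)):
                        return k
        return 0

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        det = rng.uniform(0, 60, size=(int(rng.integers(0, 7)), 2))
        tru = rng.uniform(0, 60, size=(int(rng.integers(0, 7)), 2))
        radius = float(rng.choice([5.0, 10.0, 30.0]))
        if match_frame(det, tru, radius).n_tp == optimal_tp(det, tru, radius):
            agree += 1
    return {"n_instances": n_instances, "n_agree": agree}
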