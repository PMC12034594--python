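"""Phantom generator: geometry, determinism, occlusion bookkeeping, physio."""

import numpy as np
import pytest

from fluorofuse import PhantomSpec, generate_catheter_path, generate_dataset, generate_physio
from fluorofuse.phantom import PhantomGeometryError, _sensor_arcs, render_frame


class TestSpecValidation:
    def test_overlapping_sensors_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            PhantomSpec(spacing_px=10.0, sensor_len_px=13.0)

    def test_fps_outside_clinical_range_rejected(self):
        with pytest.raises(ValueError, match="fps"):
            PhantomSpec(fps=30.0)

    def test_unknown_noise_level_rejected(self):
        with pytest.raises(ValueError, match="noise_level"):
            PhantomSpec(noise_level="extreme")


class TestCatheterPath:
    def test_zero_amplitude_gives_vertical_line(self):
        spec = PhantomSpec(seed=4, curve_amplitude_px=0.0, drift_px=0.0)
        path = generate_catheter_path(spec, 0)
        assert len(path) == spec.image_size[0]
        assert np.ptp(path.cols) == 0.0

    def test_same_seed_and_frame_reproduces_polyline(self):
        spec = PhantomSpec(seed=9)
        a = generate_catheter_path(spec, 3)
        b = generate_catheter_path(spec, 3)
        np.testing.assert_array_equal(a.cols, b.cols)

    @pytest.mark.parametrize("frame_idx", [0, 5, 20])
    def test_frame_to_frame_drift_is_slow(self, frame_idx):
        spec = PhantomSpec(seed=2, curve_amplitude_px=80.0)
        a = generate_catheter_path(spec, frame_idx)
        b = generate_catheter_path(spec, frame_idx + 1)
        assert np.max(np.abs(a.cols - b.cols)) <= 3.0

    def test_excursion_bounded_by_amplitude(self):
        spec = PhantomSpec(seed=5, curve_amplitude_px=30.0, drift_px=0.0)
        path = generate_catheter_path(spec, 0)
        center = np.mean([path.cols.min(), path.cols.max()])
        assert np.max(np.abs(path.cols - center)) <= 30.0 + 1e-6


class TestRenderFrame:
    def test_sensors_are_local_minima_along_path(self):
        spec = PhantomSpec(seed=3, noise_level="none")
        path = generate_catheter_path(spec, 0)
        img, truth = render_frame(spec, path, 0, np.random.default_rng(0))
        img = img.astype(float)
        for t in truth:
            r, c = int(round(t.row)), int(round(t.col))
            here = img[r, c]
            # flanking points half a spacing up/down the (mostly vertical) path
            off = int(spec.spacing_px // 2)
            assert here < img[max(r - off, 0), c]
            assert here < img[min(r + off, img.shape[0] - 1), c]

    def test_noise_does_not_move_ground_truth(self):
        quiet = PhantomSpec(seed=6, noise_level="none")
        loud = quiet.replace(noise_level="most")
        path = generate_catheter_path(quiet, 0)
        img_q, truth_q = render_frame(quiet, path, 0, np.random.default_rng(1))
        img_l, truth_l = render_frame(loud, path, 0, np.random.default_rng(1))
        assert [(t.index, t.row, t.col) for t in truth_q] == [
            (t.index, t.row, t.col) for t in truth_l
        ]
        assert np.any(img_q != img_l)

    def test_visible_sensor_count_tracks_request(self):
        # ~30 sensors visible per frame at native scale
        spec = PhantomSpec.full_scale(seed=0, n_visible=26)
        path = generate_catheter_path(spec, 0)
        _, truth = render_frame(spec, path, 0, np.random.default_rng(0))
        assert len(truth) == 26

    def test_impossible_geometry_raises(self):
        spec = PhantomSpec(seed=0, image_size=(40, 40), spacing_px=80.0, sensor_len_px=60.0)
        path = generate_catheter_path(spec, 0)
        with pytest.raises(PhantomGeometryError):
            _sensor_arcs(spec, path)

    def test_occluded_sensors_lie_inside_saturated_bolus(self):
        spec = PhantomSpec(
            seed=8, bolus_enabled=True, bolus_speed_px_per_frame=0.0, bolus_start_frac=0.5
        )
        path = generate_catheter_path(spec, 0)
        img, truth = render_frame(spec, path, 0, np.random.default_rng(0))
        occluded = [t for t in truth if t.occluded]
        assert len(occluded) >= 4
        for t in occluded:
            assert img[int(round(t.row)), int(round(t.col))] <= 10

    def test_bottom_end_numbering(self):
        spec = PhantomSpec(seed=2, visible_end="bottom")
        path = generate_catheter_path(spec, 0)
        _, truth = render_frame(spec, path, 0, np.random.default_rng(0))
        # lowest sensor in the frame must be hardware sensor 36
        lowest = max(truth, key=lambda t: t.row)
        assert lowest.index == 36
        idx_sorted_by_row = [t.index for t in sorted(truth, key=lambda t: t.row)]
        assert idx_sorted_by_row == sorted(idx_sorted_by_row)


class TestGroundTruthGeometry:
    def test_consecutive_spacing_within_ten_percent(self, small_dataset):
        _, truth, _ = small_dataset
        spec = PhantomSpec(seed=1, n_frames=6)
        for frame in truth.per_frame:
            pts = np.array([[t.row, t.col] for t in frame])
            gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            assert np.all(gaps >= 0.9 * spec.spacing_px)
            assert np.all(gaps <= 1.1 * spec.spacing_px)

    def test_indices_strictly_increasing_from_visible_end(self, small_dataset):
        _, truth, _ = small_dataset
        for frame in truth.per_frame:
            idx = [t.index for t in frame]
            assert idx == sorted(idx) and len(set(idx)) == len(idx)
            assert idx[0] == 1  # visible_end == top


class TestPhysio:
    def test_channel_counts_and_duration(self):
        spec = PhantomSpec(seed=0, n_frames=40, fps=10.0)  # 4 s
        rec = generate_physio(spec, np.random.default_rng(0))
        assert rec.mano.shape == (36, 200)
        assert rec.imped.shape == (15, 200)

    def test_wave_peak_time_increases_along_catheter(self):
        spec = PhantomSpec(seed=0)
        rec = generate_physio(spec, np.random.default_rng(0))
        peaks = rec.mano.argmax(axis=1)
        assert np.all(np.diff(peaks) > 0)

    def test_impedance_drops_during_wave_passage(self):
        spec = PhantomSpec(seed=0)
        rec = generate_physio(spec, np.random.default_rng(0))
        assert np.all(rec.imped.min(axis=1) < 0.5 * rec.imped.max(axis=1))

    def test_determinism(self):
        spec = PhantomSpec(seed=0)
        a = generate_physio(spec, np.random.default_rng(7))
        b = generate_physio(spec, np.random.default_rng(7))
        np.testing.assert_array_equal(a.mano, b.mano)
        np.testing.assert_array_equal(a.imped, b.imped)


class TestGenerateDataset:
    def test_timestamps_and_duration(self):
        spec = PhantomSpec(seed=0, n_frames=40, fps=10.0)
        seq, _, _ = generate_dataset(spec)
        assert seq.duration == pytest.approx(4.0)
        np.testing.assert_allclose(seq.timestamps[:3], [0.0, 0.1, 0.2])
        assert seq.timestamps[-1] == pytest.approx(3.9)

    def test_default_frame_count_in_clinical_range(self):
        assert 40 <= PhantomSpec().n_frames <= 180

    def test_bit_identical_for_same_seed(self):
        spec = PhantomSpec(seed=42, n_frames=3, noise_level="medium")
        a, ta, pa = generate_dataset(spec)
        b, tb, pb = generate_dataset(spec)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(pa.mano, pb.mano)
        assert [(t.index, t.row, t.col, t.occluded) for f in ta.per_frame for t in f] == [
            (t.index, t.row, t.col, t.occluded) for f in tb.per_frame for t in f
        ]
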