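"""Line-stage heatmap, extraction, and temporal error correction."""

import numpy as np
import pytest

from fluorofuse import (
    CatheterLine,
    CatheterParams,
    DetectorParams,
    LineDetectionError,
    LineHistory,
    PhantomSpec,
    extend_full_height,
    extract_line,
    generate_catheter_path,
    ncc_heatmap,
    temporal_correct,
)
from fluorofuse.catheter import SequenceStartError
from fluorofuse.phantom import render_frame
from fluorofuse.preprocess import enhance
from fluorofuse.templates import template_bank, triples


@pytest.fixture(scope="module")
def triple_templates():
    spec = PhantomSpec()
    return triples(DetectorParams.for_phantom(spec).bank())


class TestHeatmap:
    def test_constant_image_scores_zero_inside_valid_region(self, triple_templates):
        hm = ncc_heatmap(np.full((200, 200), 0.5), triple_templates)
        assert hm.shape == (200, 200)
        assert np.all(hm[100] <= 0.0 + 1e-9)
        assert np.allclose(hm[100, 100], 0.0)
        assert hm[0, 0] == -1.0  # sentinel border

    def test_combined_map_is_elementwise_max(self, triple_templates):
        rng = np.random.default_rng(0)
        img = rng.random((150, 150))
        separate = [ncc_heatmap(img, [t]) for t in triple_templates]
        combined = ncc_heatmap(img, triple_templates)
        np.testing.assert_allclose(combined, np.maximum(*separate))

    def test_invariant_to_affine_intensity_rescaling(self, triple_templates):
        rng = np.random.default_rng(1)
        img = rng.random((150, 150))
        a = ncc_heatmap(img, triple_templates)
        b = ncc_heatmap(0.4 * img + 0.2, triple_templates)
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_image_smaller_than_template_rejected(self, triple_templates):
        with pytest.raises(ValueError, match="larger"):
            ncc_heatmap(np.zeros((10, 10)), triple_templates)

    def test_peak_near_true_sensor_on_phantom(self, triple_templates):
        spec = PhantomSpec(seed=5, noise_level="none")
        path = generate_catheter_path(spec, 0)
        img, truth = render_frame(spec, path, 0, np.random.default_rng(0))
        hm = ncc_heatmap(
            enhance(img), triple_templates, CatheterParams().rotations
        )
        r, c = np.unravel_index(np.argmax(hm), hm.shape)
        assert min(np.hypot(r - t.row, c - t.col) for t in truth) <= 3.0


class TestExtractLine:
    def test_single_bright_column(self):
        hm = np.full((100, 80), -0.2)
        hm[:, 37] = 0.9
        line = extract_line(hm, CatheterParams())
        assert line.span == (0, 99)
        assert np.all(line.cols == 37)

    def test_slope_constraint_holds_on_output(self):
        rng = np.random.default_rng(3)
        hm = rng.uniform(-0.5, 0.29, (120, 60))
        c = 30 + np.cumsum(rng.uniform(-1, 1, 120)).clip(-20, 20)
        hm[np.arange(120), c.astype(int)] = 0.9
        line = extract_line(hm, CatheterParams())
        assert np.all(np.abs(np.diff(line.cols)) <= CatheterParams().max_slope_px)

    def test_all_scores_below_floor_fails(self):
        with pytest.raises(LineDetectionError):
            extract_line(np.full((100, 80), 0.1), CatheterParams())

    def test_short_run_fails(self):
        hm = np.full((200, 80), -0.5)
        hm[:40, 20] = 0.9  # only 20% of height
        with pytest.raises(LineDetectionError):
            extract_line(hm, CatheterParams())

    def test_phantom_line_tracks_true_catheter(self, triple_templates):
        spec = PhantomSpec(seed=5, noise_level="none")
        path = generate_catheter_path(spec, 0)
        img, _ = render_frame(spec, path, 0, np.random.default_rng(0))
        hm = ncc_heatmap(enhance(img), triple_templates, CatheterParams().rotations)
        line = extract_line(hm, CatheterParams())
        err = np.abs(line.cols - path.cols[line.rows])
        assert err.mean() <= 3.0


class TestExtendFullHeight:
    def test_covers_full_height_with_clamped_slope(self):
        line = CatheterLine(rows=np.arange(100, 300), cols=np.linspace(50, 70, 200))
        full = extend_full_height(line, 512)
        assert full.span == (0, 511)
        assert np.all(np.abs(np.diff(full.cols)) <= 3.0 + 1e-9)
        # interior untouched
        np.testing.assert_allclose(full.cols[100:300], line.cols)


def _line(cols_value: float, n: int = 100) -> CatheterLine:
    return CatheterLine(rows=np.arange(n), cols=np.full(n, cols_value), quality=0.8)


class TestTemporalCorrect:
    def test_zero_deviation_accepted_unchanged(self):
        hist = LineHistory()
        for i in range(3):
            temporal_correct(_line(40.0), hist, i)
        accepted, corrected = temporal_correct(_line(40.0), hist, 3)
        assert not corrected
        assert np.all(accepted.cols == 40.0)

    def test_large_displacement_replaced_by_history_average(self):
        hist = LineHistory()
        for i in range(3):
            temporal_correct(_line(40.0), hist, i)
        accepted, corrected = temporal_correct(_line(140.0), hist, 3, dev_thresh_px=30.0)
        assert corrected
        np.testing.assert_allclose(accepted.cols, 40.0)

    def test_failure_falls_back_to_history(self):
        hist = LineHistory()
        for i in range(3):
            temporal_correct(_line(55.0), hist, i)
        accepted, corrected = temporal_correct(None, hist, 3)
        assert corrected
        np.testing.assert_allclose(accepted.cols, 55.0)

    def test_first_frame_failure_is_unrecoverable(self):
        with pytest.raises(SequenceStartError):
            temporal_correct(None, LineHistory(), 0)

    def test_history_window_is_three(self):
        hist = LineHistory()
        for i in range(5):
            temporal_correct(_line(float(i)), hist, i, dev_thresh_px=100.0)
        assert len(hist) == 3
        np.testing.assert_allclose(hist.average().cols, np.mean([2.0, 3.0, 4.0]))

    def test_correction_propagates_through_history(self):
        # a corrected line enters the history and anchors later frames
        hist = LineHistory()
        for i in range(3):
            temporal_correct(_line(40.0), hist, i)
        temporal_correct(None, hist, 3)  # correction: average pushed
        accepted, corrected = temporal_correct(_line(120.0), hist, 4, dev_thresh_px=25.0)
        assert corrected and np.allclose(accepted.cols, 40.0)


def test_occluded_frame_line_recovered_within_ten_px_rms():
    """A frame whose catheter is wiped by the bolus still yields a line
    within 10 px RMS of truth, via bridging and temporal correction."""
    spec = PhantomSpec(
        seed=7,
        n_frames=12,
        bolus_enabled=True,
        bolus_speed_px_per_frame=0.0,
        bolus_start_frac=0.45,
    )
    from fluorofuse import detect_sequence, generate_dataset

    frames, truth, _ = generate_dataset(spec)
    res = detect_sequence(frames.frames, DetectorParams.for_phantom(spec))
    # pick frames with heavy occlusion
    heavy = [i for i in range(12) if sum(t.occluded for t in truth.frame(i)) >= 5]
    assert heavy
    for i in heavy[:4]:
        path = generate_catheter_path(spec, i)
        line = res.lines[i]
        err = line.cols - path.cols[line.rows]
        assert np.sqrt(np.mean(err**2)) <= 10.0
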