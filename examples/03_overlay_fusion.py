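"""Fuse manometry/impedance values onto the detected sensor positions.

For one frame, the synchronized 50 Hz pressure sample of each detected
sensor is color-coded (Clouse-plot-style ramp) and painted as a ribbon
along the catheter; impedance channels - each measured between every
second sensor starting from the fourth - form a second, laterally offset
ribbon.  The overlay PNG is written next to this script's working dir.
"""

import imageio.v3 as iio

from fluorofuse import (
    DetectorParams,
    PhantomSpec,
    detect_sequence,
    generate_dataset,
    impedance_span,
    render_overlay,
    sync_sample_index,
)

spec = PhantomSpec(seed=1, n_frames=20)
frames, _, physio = generate_dataset(spec)
result = detect_sequence(frames.frames, DetectorParams.for_phantom(spec))

frame_idx = 10
t = float(frames.timestamps[frame_idx])
overlay = render_overlay(
    frames.frames[frame_idx],
    result.lines[frame_idx],
    result.sensor_sets[frame_idx],
    physio,
    t,
)
iio.imwrite("overlay_frame10.png", overlay.image)

sample = sync_sample_index(t, physio.rate, physio.n_samples)
sensors = result.sensor_sets[frame_idx].by_index()
print(f"frame {frame_idx} at t={t:.2f} s -> physiology sample {sample}")
print(f"impedance channel 1 spans sensors {impedance_span(1)}, "
      f"channel 15 spans {impedance_span(15)}")
for idx in (1, 10, 20):
    if idx in sensors:
        p = physio.mano[idx - 1, sample]
        print(f"  sensor {idx:2d}: pressure {p:7.1f} mmHg at "
              f"({sensors[idx].row:.0f}, {sensors[idx].col:.0f})")
print("wrote overlay_frame10.png")
# The ribbon color at each sensor equals the colormap of its pressure at
# the synchronized sample; values between sensors are interpolated.
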