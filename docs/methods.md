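# Methods

`fluorofuse` detects the 36 pressure sensors of a high-resolution
esophageal manometry catheter in low-dose X-ray videofluoroscopy
sequences and projects synchronized manometry and impedance values onto
the detected positions. Low-dose sequences are noisy and low-contrast,
the catheter course varies between patients, and swallowed contrast
agent (bolus) can hide whole stretches of the catheter, so the detector
is built around template matching with explicit temporal and geometric
error correction rather than per-frame appearance alone. Because
clinical recordings cannot be redistributed, the package ships a
synthetic phantom generator that emulates the acquisition and provides
exact ground truth; every quantitative claim in the test suite is made
on phantom data and should be read as such.

## Acquisition model and the phantom

The emulated acquisition: 8-15 frames/s grayscale X-ray at a native
1024x1024 resolution; a catheter with 36 sensors spaced 1 cm apart,
appearing as dark bars roughly 25-30 px long at 35-40 px spacing; around
30 sensors inside the field of view; manometry (36 channels, mmHg) and
impedance (15 channels, Ohm) sampled at 50 Hz on the same clock as the
video. The 15 impedance channels sit between every second sensor
starting from the fourth, so channel k spans sensors (2+2k, 4+2k) -
fifteen spans tiling sensors 4 through 34.

The phantom (`fluorofuse.phantom`) renders, per frame:

* a smooth background of low-frequency sinusoidal gradients with a mild
  vignette and slow exposure flicker (anatomy and windowing stand-ins);
* a catheter path: a two-harmonic sinusoid in the row coordinate with
  bounded horizontal excursion (`curve_amplitude_px`, default 40 px at
  512 scale) plus a slow sideways drift (<= ~1 px/frame, emulating
  breathing/patient motion);
* dark soft-edged sensor bars at fixed arc-length multiples of the
  spacing along the path, oriented with the local tangent;
* optionally a radiopaque bolus: an elongated blob moving along the
  path, rendered *saturating* (it drives the image to black). This
  matters: normalized cross-correlation is invariant to local contrast,
  so a merely translucent dark blob would leave sensors detectable and
  produce no occlusion at all. A sensor is flagged `occluded` in the
  ground truth only when its center and both bar ends lie inside the
  bolus footprint - sensors whose tip pokes past the sharp (2 px) bolus
  edge remain partially visible and are not occluded;
* additive Gaussian noise at one of four named levels, with sigmas
  0 / 10 / 25 / 50 on the 8-bit scale ("none" / "little" / "medium" /
  "most"). Noise never moves the ground truth.

Defaults are the half-scale geometry (512x512, spacing 19 px, sensor
length 13 px), which keeps full studies fast while preserving every
ratio of the native setup; `PhantomSpec.full_scale()` switches to
1024x1024. At 512 scale roughly 26-29 sensors fit in frame. Everything -
frames, truth, physiology - is a deterministic function of the spec
including its seed.

The physiology generator produces one peristaltic contraction: a
Gaussian-profile pressure wave travelling from channel 1 to 36 across
the central 80 % of the record (amplitude 120 mmHg over a ~5 mmHg
baseline), and an impedance drop (1800 -> ~300 Ohm) co-propagating with
it, which is the canonical Clouse-plot structure. What the phantom does
*not* model: real anatomy, scatter/beam hardening, catheter coiling,
double swallows, or pathological motility - so passing tests demonstrate
the pipeline's mechanics and robustness model, not clinical performance.

## Preprocessing

Fixed order: crop -> Gaussian blur -> CLAHE. Uniform borders (intensity
range <= `border_uniformity_tol`, default 2/255) are stripped by
re-scanning all four edges to a fixed point, which makes cropping
idempotent; detections are mapped back through the crop offset. Blur
(`blur_sigma` = 1.5 px) precedes CLAHE because local equalization
amplifies noise. CLAHE uses an 8x8 tile grid and clip limit 2.0 in the
OpenCV-style convention (converted internally to scikit-image's
histogram fraction as 2.0/256). The sources describe the recipe but not
its parameters; these defaults are config-overridable.

## Stage 1 - catheter line

Two templates showing three stacked sensor bars (a "large" and a "small"
sensor geometry, bracketing the nominal size by +-1/9) are matched by
normalized cross-correlation; the heatmap is the element-wise maximum.
NCC is used because it is invariant to the affine intensity changes that
dominate fluoroscopy (windowing, exposure). Scores sit at template
centers; border pixels where a template does not fit carry a sentinel
score of -1, and zero-variance windows score 0.

A three-bar stack is long (~120 px at native scale), so it decorrelates
completely when the catheter is locally tilted; matching therefore also
runs over rotated template variants (+-36 degrees in 12-degree steps,
`CatheterParams.rotations`). Without this the line stage measurably
fails on curved phantom catheters while background responses (0.3-0.5
NCC after CLAHE) take over.

Line extraction takes each row's score argmax as a candidate and finds
the *maximum-weight chain* of candidates (dynamic programming). Two
candidates can be chained when their row gap is at most `gap_max`
(160 rows - large enough to bridge a bolus-sized hole) and their column
change respects a bridge-aware slope rule: the full `max_slope_px`
(3 px/row) applies only over the first few rows, with 1 px/row allowed
sustained across longer gaps. The second part matters: a plain
slope-times-gap bound lets a modest gap absorb a large sideways jump
onto a structure running parallel to the catheter (typically the bolus
edge), which was the dominant failure mode in occluded frames. Chain
weight is the score margin above `score_floor` (0.3), so a short strong
catheter segment beats a long chain of weak background responses, and
single outlier candidates are skipped rather than splitting the line.
Gaps inside the chain are filled by linear interpolation - across a
bolus this is a near-straight chord whose error is bounded by the
curve's sagitta (<= ~10 px at the default curvature). A chain spanning
less than half the image height is a detection failure.

Temporal correction keeps the last three accepted lines; the current
line is replaced by their per-row average when detection failed or when
its RMS per-row column deviation from that average exceeds
`dev_thresh_px` (15 px, about twice the largest routine deviation from
drift plus bridging error). RMS rather than a plain mean is used because
the characteristic bolus failure corrupts one stretch of the line while
agreeing elsewhere, and a plain mean dilutes it below any workable
threshold. The accepted line enters the history, so corrections
propagate. A failure on the very first frame is unrecoverable by
construction and raises.

The accepted line is finally extrapolated to full frame height with the
least-squares slope of its last 25 rows (clamped to the slope bound):
the heatmap's sentinel margins mean a detected line never reaches the
frame edges, but sensors living there (including the numbering anchor)
still need grid slots.

## Stage 2 - single sensors

A second heatmap from two single-sensor templates is sampled bilinearly
at 1 px arc-length steps along the line. Candidate peaks are local
maxima scoring at least `peak_floor` (0.45); the emitted subset
maximizes total score subject to a minimum separation of 0.6x the
nominal spacing, solved exactly by dynamic programming (for
well-separated sensors this is ordinary non-maximum suppression, but the
exact solution also handles pathological bump clusters and makes the
exhaustive-enumeration oracle an identity). The floor of 0.45 sits
between measured real-sensor peaks (>= 0.56 even at the heaviest noise
level) and bolus-edge artifacts (<= ~0.42).

Peaks are snapped to a regular arc grid at the locally estimated spacing
(median inter-peak gap, with gaps near spacing multiples folded back,
clipped to nominal +-20 % - esophageal bending changes the apparent
spacing within a frame). Grid slots without a supporting peak become
sensors with `inferred=True` at the interpolated (interior) or
extrapolated (end) arc position, as long as the slot stays a
sensor-footprint margin (0.35x spacing) inside the line span; their
confidence is the profile score there. Numbering is anchored at the
visible catheter end - a dataset-level setting, since sequences are
deliberately acquired with either the top or the bottom of the catheter
in frame: index 1 at the top, or index 36 at the bottom counting
backward. Fewer than three supporting peaks mark the frame
low-confidence. Sensor positions are *not* smoothed over time; only the
line is, which keeps the two error-correction mechanisms separable.

## Fusion

Frames and physiology share one clock, so each frame takes the nearest
50 Hz sample (error <= 10 ms at <= 15 fps; no temporal interpolation).
Pressures are clamped into a display range (-10..150 mmHg default),
mapped through a Clouse-style blue-to-red ramp ("jet"), interpolated
linearly in arc length between sensor centers (no extrapolation past the
outermost sensors), and painted as a ~8 px ribbon along the line.
Impedance (50..2000 Ohm, log-scaled by default) forms a second ribbon at
a lateral offset, anchored at each channel's sensor-pair midpoint.
Inferred sensors are rendered exactly like detected ones - that is the
point of inferring them. Rendering is a pure function of its inputs;
pixels off the ribbons are untouched, and the pixel at each sensor
center carries exactly `colormap(clamped value)`.

## Evaluation

A detection is correct within a tolerance radius of an unmatched truth
sensor; the three radii 5/10/30 px define the "exact" / "good" /
"acceptable" levels. Matching is one-to-one and optimal (maximum matches
within the radius, ties broken toward smallest total distance, via
linear assignment). An earlier greedy distance-ordered matcher was
abandoned after a counterexample showed it under-counting true positives
on dense instances, which would have broken the intended equivalence
with exhaustive matching; with the assignment formulation that
equivalence is a theorem, and the test suite still verifies it against
brute-force enumeration on small instances. Inferred sensors count as
ordinary detections. Counts are pooled within a sequence, and P/R/F1 are
averaged across sequences with a standard deviation, mirroring
per-patient reporting. Zero-detection/zero-truth reports are flagged
undefined (NaN), never silently zero. The noise study adds Gaussian
noise to already-rendered clean frames (emulating noise on acquired
images) and reruns the full pipeline per level against the shared truth.

## Study sizes and numerical choices

The canonical studies (`fluorofuse.studies`, also used by
`scripts/acceptance.py`) run at sizes chosen to make their statistics
stable while keeping a full run in minutes on one CPU: clean study 5
sequences x 40 frames (512x512), noise study 3 sequences x 15 frames x 4
levels, occlusion study one 30-frame sequence with a six-spacing bolus
sweeping the mid-catheter band at 8 px/frame (starting below the
numbering anchor: a bolus parked over a catheter end from the first
frame hides geometry no method could ever have observed, whereas
mid-swallow transit is the representative clinical case), matcher oracle
200 random instances of up to 6 points per side. All randomness flows
from explicit seeds; reruns are bit-identical.

Degenerate inputs are defined rather than special-cased where possible:
constant images score 0 under NCC; a fully uniform image is an error for
cropping (there is no content); an empty peak list yields an empty
sensor set flagged low-confidence; out-of-range physiology times clamp
to the record end with a warning.

## Known limitations

* Strongly horizontal or coiled catheters are out of scope: row-wise
  extraction assumes a mostly vertical course (true of the intended
  acquisitions), and the rotation fan stops at +-36 degrees.
* When the numbering anchor (first/last sensor) is occluded, its slot is
  extrapolated from the spacing grid; the index phase can then be off by
  one until the anchor reappears. Position accuracy is unaffected.
* Temporal correction assumes slow anatomy drift; a correction streak
  longer than a few frames effectively freezes the line at the last
  good average.
* The phantom's noise is additive Gaussian only (no Poisson/quantum
  mottle), and its background is smooth; real low-dose texture is
  harsher on CLAHE.
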