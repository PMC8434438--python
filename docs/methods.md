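# Methods

`depthact` recognises the daily actions of a monitored person from a
ceiling-mounted stereo depth camera that records nothing but per-frame
depth grids (320×180 px, 1 fps, distances in metres).  This note
documents the processing model, the tunable parameters, the synthetic
scene generator used as ground truth, and the numerical choices made
where the design was open.

## Processing model

**Pre-processing.**  Depth frames contain holes (0-valued pixels where
the sensor lost range) and per-pixel range noise.  Holes are filled
row-wise from the nearest valid pixel to the left; leading holes with no
valid pixel to their left are backfilled from the first valid pixel of
the row, so any row with one valid measurement ends hole-free and the
operation is idempotent.  An edge-preserving bilateral filter (window
5 px, range sigma 0.1 m, spatial sigma 3 px) then suppresses range noise
without smearing object boundaries.  The static background is the
pixel-wise mean of the first 30 person-free frames; pixels whose mean
depth exceeds `far_threshold` (6 m — near the sensor's reliable range)
are masked out of all later processing because far-range readings are
unstable.

**Region extraction.**  Depth is converted to disparity
(d_px = f·b/Z, inversely proportional to depth) and quantised into
`n_disparity_levels` = 128 bins spanning disparities from zero up to the
disparity at `min_depth` = 1 m, i.e. bin = round(127·min_depth/Z).
Quantising the *sub-pixel* disparity rather than rounding to whole
pixels is deliberate: with a short-baseline camera (f = 160 px,
b = 0.05 m) a whole room spans fewer than eight integer-pixel disparity
values, far too coarse for line detection, while 128 quantisation bins
resolve the room's depth structure.  The V-disparity map (per-row
disparity histogram) turns the floor into a slanted straight line (the
ground correlation line), detected by a Hough transform restricted to
slants of 20°–80° from the disparity axis — flat vertical surfaces
project at 90° and are thereby excluded.  A pixel is floor iff its
disparity bin lies within ±1 bin of the line at its row.  After zeroing
floor pixels, the V-disparity map is rebuilt, binarised at ≥5 counts,
and its largest 8-connected component (weighted by represented pixel
count) is taken as the bed; the component's four extremes (min/max image
row, min/max disparity) delimit the bed pixels.  Everything else is the
ignored region; where floor and bed claim the same pixel, floor wins.

A person blob is located by region overlap: on the *bed* if more than
70 % of its pixels fall in the bed region, otherwise on the *floor* if
more than 30 % fall in the floor region, otherwise *other*.  The bed
test runs first; the floor test is the fallback branch.

**Curtain removal.**  A hanging curtain is a flat vertical surface, so
its foreground pixels trace a straight line across columns of the
U-disparity map (per-column disparity histogram).  The strongest
non-vertical Hough line supported by at least `curtain_min_cols` = 120
distinct columns is taken as the curtain, and foreground pixels within
±8 bins (≈ half a pixel of disparity — a vertical surface seen by a
tilted camera spreads over several quantisation bins per column) of the
line at their column are removed.  The line is not extrapolated past its
histogram support, and the column-span requirement keeps compact person
blobs (≲100 columns) from ever being classified as curtain.

**Foreground and tracking.**  A pixel is foreground iff the background
is deeper than the current frame by at least 0.2·σ(I), where σ(I) is the
standard deviation of the current frame's valid depths (floor of 0.05 m
if σ degenerates to 0).  The test is one-sided: only objects *nearer*
than the background count.  Masks are cleaned by morphological opening
then closing (3×3, 8-connected), curtain subtraction, and removal of
blobs under 100 px.  Blobs are tracked by a three-gate association rule
between consecutive frames — centroid distance < 30 px, area difference
< 5000 px, mean-depth difference < 0.5 m — with greedy nearest-centroid
conflict resolution; lost tracks survive a 5-frame grace period.  A
track is confirmed as a *person* when motion (sum of absolute per-pixel
depth changes inside its bounding box exceeding 80) is observed in
strictly more than six of the last ten frames; the confirmed flag is
sticky.  The motion sum uses |ΔD| rather than the signed sum, which
would cancel for oscillating motion.

**Features.**  The person's silhouette is cropped, isotropically
downscaled if needed, and centred on a 256×176 zero-padded canvas
(256 wide × 176 high: 16 × 11 cells of 16 px).  Two temporal templates
accumulate over a recognition window: DMA (depth motion appearance),
the pixel-wise running minimum of depth — canvas padding (D_t = 0) is
treated as absence of data and never enters the minimum — and DMH
(depth motion history), set to τ = 30 frames wherever
|D_t − D_{t−1}| > δ = 0.01 m and decremented toward zero elsewhere.
The absolute difference is used because a person moving *away* from the
camera must trigger history just as one approaching does.  Each map
yields a HOG descriptor: centred-difference gradients, unsigned
orientations on [0°, 180°) hard-binned into 9 sectors weighted by
magnitude, one histogram per 16×16 cell, each cell L2-normalised as its
own 1×1 block with ε = 10⁻⁶, giving 16·11·9 = 1584 values; the DMA and
DMH descriptors are concatenated (DMA first) into the 3168-dim fused
feature.  Raw depth in metres is kept on the canvas (no [0,1]
rescaling); per-block contrast normalisation makes HOG insensitive to
the absolute scale.

Separately, the floor pixels are back-projected through the pinhole
model (X = Z(x−c_x)/f, Y = Z(y−c_y)/f) and a total-least-squares plane
aX+bY+cZ+d = 0 (unit normal, c ≥ 0) is fitted via the eigenvector of
the smallest covariance eigenvalue.  TLS is used because pixel "vertical
least squares" would be ill-posed for steep viewing angles.  The
person's height is the signed distance of their back-projected 2-D
centroid (at the blob's mean depth) from this plane, oriented positive
above the floor: a downward-looking camera always yields d < 0 after
c ≥ 0 normalisation, so the sign of d orients the plane.

**Recognition.**  A multi-class linear SVM (pairwise Platt-calibrated
probabilities, deterministic under a seed) is trained on fused features
of short labelled sequences (5–30 frames) of the five trainable actions:
Transition (1), Seated in wheelchair (2), Standing (3), Sitting on the
bed (4), Lying on the bed (5).  The height feature is *not* an SVM
input.  Long sequences are segmented online by automatic rounding: the
window grows frame by frame (maps updated incrementally, reset at round
start); from the minimum round length of 5 frames on, the round closes
as soon as the top class probability reaches `th_prob` = 0.30, and at
the maximum duration of 30 frames it closes as *undetermined*.  The
probability threshold is stored as a probability (0.30): any other
reading would be incommensurable with a classifier posterior.  At round
close the label is checked against context: a blob whose median height
over the round exceeds Th_assist = 1.0 m becomes Receiving
assistance (6) — a resident-plus-nurse silhouette is taller than the
resident alone; one whose height is below Th_fall = 0.4 m while located
on the floor becomes Falling (7); a Lying label off the bed region is
demoted to undetermined.  The round's modal location and median height
are used rather than single-frame values, which are noisier.  Frames
with no confirmed person are labelled Outside the room (0).  Optionally
a block median filter condenses every 5 consecutive labels into their
(lower) median — 600 frames become 120 outputs.  Accuracy is per-frame
against ground truth with undetermined frames excluded from the
denominator (the recogniser abstained there); the confusion matrix is
actual × predicted over the evaluated frames.

## The synthetic scene generator

No public recording of the monitored bedrooms exists, so the package
ships a parametric simulator that renders the study conditions: a
pinhole camera 2.1 m above the floor tilted 25° downward (f = 160 px,
baseline 0.05 m, principal point at the image centre), a floor plane, a
0.45 m-high bed cuboid, a wheelchair-sized box, an optional partially
drawn curtain, and a person composed of four ellipsoids (shins, thighs,
torso, head) whose arrangement encodes posture — standing, seated
(shins dropping below the seat to the floor), lying — with linear
morphing between postures for transitions.  The default body is a
1.55 m elderly resident.  Depth is the distance along the optical axis
(matching the back-projection used downstream), saturates at the
sensor range of 6.5 m, and is corrupted by Gaussian noise
(σ = 0.02 m) plus uniformly random holes (5 % of pixels) — values
chosen as typical of short-baseline stereo depth at room distances.
Ground truth per sequence: per-frame action labels, per-frame person
masks, the floor/bed/ignored region map of sensed surfaces, and the
analytic floor plane in camera coordinates.

The generator reproduces the geometric and radiometric structure the
pipeline consumes — occlusion (a wheelchair hides the sitter's legs; the
person occludes the room), posture-dependent silhouettes, depth noise,
holes, sensor saturation.  It does not model cloth, articulated limbs,
multi-person interaction, blankets, or sensor-specific artefacts such
as edge flying pixels; passing tests therefore demonstrate the
*mechanics* of the pipeline under controlled conditions, not clinical
performance on real recordings.

The benchmark script is a 600-frame scripted day: 60 empty frames
(background lead-in), entry in the wheelchair, 100 s seated, standing
up, 80 s standing/walking, sitting on the bed (140 s), lying down
(184 s), with 8-frame transitions — mirroring the typical routine of a
care-center resident.  Training uses 16 jittered short scripts per
trainable label (80 sequences — a scale-down of the deployment
protocol's several hundred; durations 5–30 frames, position and
body-height jitter, standing split between still-with-sway and
slow-walk variants), rendered with the same noise and pushed through
the same foreground-extraction path as testing.

## Numerical choices and degenerate inputs

- Disparity quantisation: 128 bins over [0, d(1 m)]; holes and
  far-masked pixels carry an invalid bin and never enter histograms.
- Hough: V-disparity binarised at ≥5 counts, θ resolution 0.25°,
  minimum 20 votes; no line above threshold → empty floor mask plus a
  warning, and the pipeline continues without height features.
- Plane fit requires ≥3 non-collinear points (checked via the middle
  covariance eigenvalue); floor pixels are subsampled to 2000 points.
- All-hole frames pass through hole filling unchanged (warned); σ = 0
  frames fall back to a 0.05 m subtraction threshold.
- Blob silhouettes larger than the canvas are downscaled isotropically
  with nearest-neighbour interpolation (order 0) to keep the silhouette
  boundary crisp.
- The median of a label block is the lower median, so filtered outputs
  stay in the input label set.
- Ties in greedy association are broken by centroid distance; track ids
  are allocated in blob-discovery order.

## Problem sizes

The shipped tests and the acceptance script use: 100 random 10-frame
16×16 sequences for the incremental-vs-batch map check; 20 random
frames per pixel-loop oracle; 20 seeds × 500 points (σ = 0.01 m) for
plane recovery; four camera tilts (10°–40°) for closed-loop region
extraction; one 600-frame benchmark sequence per seed, with ten seeds
for the median-filter robustness property.  These sizes keep a full run
in minutes on one CPU while exercising every stage end to end.

## Known limitations

- One resident and at most one extra (nurse) blob; the tallest person
  blob drives the height rules, and multi-blob frames are only logged.
- The background is estimated once per sequence from a person-free
  lead-in; slow scene changes (moved furniture) are not re-learned.
- Seated-in-wheelchair vs sitting-on-bed discrimination relies on
  silhouette shape and depth texture; heavy occlusion distorts both.
- The fall label is rule-based (height + floor region); no fall
  training data exists, mirroring the deployment setting.
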