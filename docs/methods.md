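# Methods

`ichthyoflow` implements the analysis chain of a flow-through imaging
system for ichthyoplankton: eggs and larvae suspended in seawater are drawn
through a back-lit tube in front of a camera with a telecentric lens, and
biologically relevant endpoints (standard length, areas, and volume
estimates) are extracted automatically from the image stream. The package
covers everything downstream of image capture and instance segmentation;
segmentation itself is an adapter boundary that accepts instance masks from
any source.

## Coordinate and unit conventions

All pixel coordinates are 0-based `(row, col)`; bounding boxes are
half-open. A single isotropic pixel scale (mm/px) converts pixels to
physical units — the telecentric lens gives an orthographic projection, so
one scalar suffices; anisotropic optics are an accepted limitation. The
scale is a required user parameter: it depends on the lens/sensor pairing
and is not hard-coded anywhere. The synthetic generator defaults to
0.0036 mm/px, the ratio of an 8.8 mm field-of-view width to 2448 sensor
columns, as a representative value for this class of hardware.

## Candidate-frame selection

The background of frame *i* is modelled as the per-pixel mean of the 50
frames nearest to *i*, **excluding frame *i* itself** — including it would
let a large object partly suppress its own detection. At the stream ends
the window is drawn from the nearest available frames, keeping its size.
A pixel is foreground when its absolute deviation from the background mean
exceeds a threshold (default 25 of 255 counts; back-lit imaging has high,
stable contrast, so a fixed absolute threshold is appropriate and the
subtraction cancels any global intensity offset exactly). Connected
components (8-connectivity by default, so thin tails stay in one piece)
are filtered by a *physical* minimum area (default 0.2 mm², converted
through the pixel scale so the rule survives resolution changes) and an
optional minimum bounding-box side. Every frame retaining at least one
blob is selected; any sub-sampling for manual annotation is a separate
downstream choice.

A static particle stuck in the flow cell enters the background mean and is
therefore *not* detected — an inherent property of moving-average
subtraction, covered by a dedicated test.

## Annotation handling

Hand-drawn outlines are smoothed with a circular moving average over the
vertex coordinates (default window 5 vertices; the filter wraps around the
closed polygon, so the vertex count and centroid are preserved exactly) and
resampled to evenly spaced points along the closed polyline (default 100),
anchored at the first vertex. Outlines persist either as vertex-per-row
CSVs (`image_id, feature_class, instance_index, point_index, row, col`,
full float precision, exact round-trip) or as lossless 8-bit PNG label
masks, one file per image per class with instances encoded as gray levels
1..n. A seeded permutation assigns images to train/validation sets
(default 90/10, realized within one item of the fraction).

For egg annotations the drawn features are the shell, the embryo and the
*non-yolk* area; the yolk mask consumed by a segmenter is derived as the
filled shell interior minus the shell ring and the non-yolk area. This
mapping is an interpretation of the annotation scheme and is labelled as
such in the code.

## Mask validation rules

Raw instance masks pass through a fixed rule set before measurement:
holes are filled; regions touching the image border are discarded; eyes
and yolks are assigned to the body whose filled mask contains the largest
fraction of their pixels (must exceed 50%); containment is enforced
against the *mask* (not the bounding box — stricter and testable), with a
configurable slack in pixels (default 0) because segmenters differ in
boundary bias; cardinality is capped at one body, two eyes and one yolk
per fish, keeping the top candidates by confidence with ties broken by
larger area and then lower centroid (deterministic, and well-defined for
segmenters that emit no confidence).

The order — fill, edge-discard, associate — matters: filling first makes
containment meaningful, and discarding edge bodies *before* association
lets interior organs survive the loss of their body. Such orphan organs
are grouped into a bodiless segmentation (retaining eye and yolk
measurements) only when no body survived and at least one body was removed
for edge contact; otherwise organs without a body are dropped, per the
association rule. `postprocess` is idempotent: re-validating its own
output segmentations reproduces them, including the bodiless case (the
segmentation carries its edge-discard context).

Two partly overlapping eyes segmented as a single figure-8 region are not
split; the region is kept and flagged `eye_shape_suspect` when its
solidity (area over convex-hull area) falls below 0.85. A genuine figure-8
with a waist falls well below this; two merely tangent discs sit near
0.88, so the flag targets waisted shapes specifically.

## Morphometry

**Standard length** is the arc length of a body centerline: the
morphological skeleton is reduced to a graph (diagonal steps weighted
√2), terminal spurs shorter than 1.5× the inscribed radius at their
junction are pruned (these are rasterization artefacts of wide regions),
the longest end-to-end path is taken, its coordinates are smoothed with a
short moving average (window 9), and both ends are extended to the mask
boundary along the terminal tangent. The reported arc length is the
Euclidean length of the smoothed polyline rather than the √2-weighted
pixel-step sum: an 8-connected pixel path overestimates lengths at
intermediate angles by up to ~8%, which would dominate the error budget;
smoothing removes that quantization while shortening smooth curves only
negligibly. A mask with no meaningful elongation (skeleton collapses, as
for a disc) falls back to the moment-ellipse major axis through the
centroid and is flagged `low_elongation`. Curved fish are measured as-is
along the curved centerline, with no straightening correction.

**Facing direction** exploits that heads are wider than tails: the mean
inscribed width (twice the distance transform) over the terminal 20% of
arc length is compared between the ends; the wider end is the head, and a
width ratio below 1.1 flags the heading ambiguous.

**Axes** of eyes, yolk sacs and egg shells are those of the ellipse with
the same second central moments as the pixel set, with the 1/12 Sheppard
correction for pixel extent, so a rasterized solid ellipse returns its own
axis lengths (within 1 px across 20–400 px sizes and arbitrary
orientations). Moment axes were preferred over Feret diameters for
robustness to boundary noise. Areas are raw pixel counts times the squared
scale — no smoothing.

The reported **eye diameter** is the measured eye *width* (minor axis), the
convention used when comparing against microscopy studies. When two eyes
are measured their axis lengths are averaged into the record.

## Volume models

With projected body area `A_L` (mm²) and standard length `L_L` (mm):

* total larva volume (cylinder): `V_L = (A_L² / L_L) · π/4`
* yolk and eye volumes (prolate spheroid from width `W` and length `L`):
  `V = (4/3) π (W/2)² (L/2)`
* structural volume: `V_S = V_L − V_Y`; a negative value (a segmentation
  fault) is retained and flagged suspect rather than clipped, preserving
  auditability
* egg volume (sphere): `D_E = (L_E + W_E)/2`, `V_E = (4/3) π (D_E/2)³`,
  with an eccentricity flag when `W_E/L_E < 0.95`

All three solids agree with independent 3-D voxel-count oracles within 1%
at 0.002 mm voxel pitch. A prolate-spheroid model of the yolk *inside*
eggs exists as a function but is excluded from egg-mode output: internal
egg features cannot be measured reliably, so only the shell is reported.

## Synthetic data

The generator renders dark objects on a bright (220-count) background with
additive Gaussian noise (σ = 5 counts, clipped to 8 bits) in pure 2-D
orthographic projection — the telecentric optics justify ignoring
perspective, and sensor-accurate noise is out of scope since the noise
only needs to exercise thresholding.

A larva is a tube swept along an arc-length-parameterized spine (circular
arc; turn 0 = straight, π = semicircle). The half-width profile tapers
from a wide head (0.21 mm) to a thin tail with a belly bump under the
yolk, and is capped at unit slope from both ends, so the silhouette
terminates exactly at the spine endpoints: the spine arc length *is* the
exact ground-truth SL. Ground-truth body area is the rendered truth-mask
pixel count times the squared scale. Eyes (two near-black ellipses,
~0.28 mm wide) and the yolk sac (mid-contrast ellipse, ~0.6 × 0.28 mm) lie
inside the body envelope by construction; within a larva the organ
intensity overrides the body, across objects the darker object wins. The
default population draws SL from a truncated Normal(4.48, 0.36) mm and egg
diameters from Normal(1.36, 0.02) mm — magnitudes typical of early
yolk-sac cod larvae and cod eggs.

Streams add a slow sinusoidal background drift (3 counts) and place each
scheduled object in exactly one frame, emulating particles carried through
the flow cell, plus sub-threshold distractor blobs (bubbles, fibres). The
curated scenario suite reproduces the documented failure modes:
edge-clipped body (organs retained), semicircular curvature, overlapping
and touching fish (one merged body with four eye candidates), and a top
view with a figure-8 merged eye region.

What the generator does **not** emulate: out-of-focus blur, refraction
through the tube wall, pigmentation texture, 3-D pose foreshortening, and
real segmenter boundary errors. Passing tests therefore demonstrate that
the *measurement chain* is correct given faithful masks — not that any
particular segmenter is accurate on real imagery.

## Validity flags instead of manual exclusion

Where a human analyst would discard extreme data points by eye, every
record carries machine-readable flags: `body_valid` is false for
edge-discarded, merged (eye-cardinality-trimmed) or degenerate bodies;
`eye_shape_suspect`, `heading_ambiguous` and `structural_volume_suspect`
mark specific doubts without discarding the numbers. An optional robust
outlier report (median ± 5 MAD) is report-only; rows are never
auto-dropped. Summaries exclude invalid rows per endpoint and report the
exclusion counts.

## Problem sizes and numerical choices

The test and acceptance runs use 100 straight + 100 curved larvae for SL
recovery, a 200-case ellipse sweep, a 200-frame stream (12 objects, 20
distractors) with an explicit-loop oracle on a 60-frame miniature, and an
end-to-end population of 40 larvae and 12 eggs — sizes chosen to give
stable statistics at desk scale. All randomness flows through explicit
seeds; renders and streams are bit-reproducible for a fixed seed. Result
CSVs are written with fixed float formatting so identical configurations
re-produce byte-identical files.

## Known limitations

* SL of strongly curled fish can be underestimated if the tail overlaps
  the body (self-occlusion is not modelled or corrected).
* Merged-eye (figure-8) regions are flagged, not split; eye volumes from
  such regions are unreliable.
* The 50%-containment association cannot disambiguate organs lying in the
  overlap of two fish; cardinality then decides, and the body is flagged.
* Single-scalar pixel scale; anisotropic optics are unsupported.
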