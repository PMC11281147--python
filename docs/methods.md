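# Methods

`trapaug` materializes augmented training sets for small-object insect
detection on sticky-trap photographs and scores detector output with
the standard mAP metrics. This note records the models, parameter
choices, numerical conventions and known limitations.

## Augmentation operators

All operators are pure functions on an `AnnotatedImage` (8-bit RGB
raster + normalized YOLO boxes); originals are never mutated.

**Photometric.** Gamma correction maps each scaled intensity
f = v/255 to `c·f^γ`; brightness–contrast applies `α·v + β` on the
0–255 scale. Both use one shared mapping for the red, green and blue
channels: trap images shot by the same device class show near-identical
per-channel intensity distributions (the `channel_histograms` utility
reproduces that inspection), so channel-wise mappings would add
parameters without adding realism. Default sampling ranges are
γ ~ U(0.2, 3.0), α ~ U(0.5, 2.0), β ~ U(−50, 50), c = 1.

**Noise.** The noise model is multiplicative speckle: each pixel is
scaled by n ~ N(1, 0.2²). A Gaussian with mean 1 and sd 0.2 is only
meaningful as a factor — added on a 0–255 scale it would be invisible —
and multiplicative graininess matches sensor/illumination noise on
field hardware. One draw per pixel location is shared across the three
channels by default (luminance rather than chroma noise);
`NoiseParams(per_channel=True)` switches to independent draws.

**Geometric.** Translation shifts the raster by the rounded pixel
offset (Δx·W, Δy·H) with Δx, Δy ~ U(−0.2, 0.2); boxes move by the exact
fractional shift, which makes translate∘translate⁻¹ exact on unclipped
boxes. Rotation (θ ~ U(−90°, 90°), counter-clockwise positive in image
coordinates) resamples bilinearly about the canvas center with the
canvas size kept fixed; a box is re-annotated as the axis-aligned
bounding box of its four rotated corners — a conservative cover, since
the annotation dialect has no rotated boxes. Vacated regions are filled
with mid-gray (114, 114, 114), the convention of the YOLO detector
family these datasets feed. Both fill color and resampling order are
configurable; nearest-neighbor (`order=0`) is exact at multiples of 90°.

**Clipping and dropping.** After any geometric mapping a box is clipped
to its containing rectangle (canvas, or mosaic quadrant). It is dropped
when the clipped area falls below 25% of the pre-clip area or either
clipped side is under 2 px: sub-2-px boxes are unlearnable and break
IoU, and the 25% visibility threshold keeps mostly-visible insects
while discarding slivers. The comparison carries a 1e−9 epsilon so a
box split exactly at the threshold (e.g. a centered box cut by a mosaic
seam into four exact quarters) is kept on all platforms.

**Rounding.** Every operator quantizes with clip-then-
round-half-away-from-zero (`floor(x + 0.5)` on the non-negative clipped
value). A fixed rule makes outputs bit-reproducible across platforms
and lets hand-computed pixel examples match exactly.

## Mosaic and modified mosaic

A mosaic rescales four sources uniformly to the S×S output canvas
(S = 320 by default, configurable) and splits the canvas at a center
drawn per-axis from U(0.5 − 0.3, 0.5 + 0.3) — the crop offset can reach
30% of the merged-image size. Each quadrant shows the same-corner-
anchored crop of its source, so with the corner anchor the pixel
mapping within each quadrant is the identity on the rescaled source and
boxes only need quadrant clipping. A random-window crop
(`crop_anchor="random"`) is available where training diversity matters
more than geometric transparency; corner-anchored is the default
because it is the construction used by the YOLO training pipelines this
emulates.

The modified mosaic applies, independently per sub-image and before
composition, brightness–contrast with probability 0.8 and noise with
probability 0.3 (two independent Bernoulli draws; both can hit the same
sub-image). Composition randomness (center, crop windows) is consumed
from the stream before any photometric draw, so setting both
probabilities to zero reproduces the plain mosaic bit-exactly under the
same seed — a property the test suite pins.

## Enrichment bookkeeping

A plan (methods, multiple k, seed, include_originals) expands n
originals to `n·(1 + k·m)` images (m = number of methods), each method
contributing one derivative per original per pass; the original set is
incorporated unless disabled. The pair strategy on 330 originals hence
yields 990 images and the triple strategy 1320. Mosaic passes compose
one mosaic per original from a seeded shuffled deck consumed four at a
time (re-shuffled in full when fewer than four remain, so the four
sources of a mosaic are always distinct and every image participates
equally).

Sub-seeding: every stream derives from numpy `SeedSequence` entropy
`[seed, method_id, pass, image_index]` with a frozen method-id table.
Adding or removing a method therefore never perturbs another method's
outputs, which keeps method-by-method ablations comparable. Manifests
record id, provenance, source ids and all sampled parameters; replaying
a manifest's plan reproduces every file byte-identically.

## Evaluation

Matching is greedy per image, class and IoU threshold: detections in
descending confidence (ties broken by input order), each taking the
unmatched same-class ground truth with the highest IoU, TP iff that
IoU ≥ t. Precision/recall accumulate along the pooled confidence sweep;
AP integrates the interpolated precision envelope over recall
(all-points method by default — the modern detector-benchmark
convention; 11-point and 101-point grids are selectable since reported
mAP values in the literature vary in this detail). mAP50 uses t = 0.5;
mAP50-95 averages the ten thresholds 0.50:0.95:0.05. With a single
class — the effective setting for codling-moth traps — mAP equals AP.
AP of an empty detection set, or with zero ground truths, is 0.

## Synthetic data

The generator emulates the geometry and photometry that make trap
images a distinct detection regime: a bright paper surface
(base ~ U(190, 230)) with a linear illumination ramp (span 25
intensity levels), Gaussian paper texture (sd 5) and a small random
per-channel tint; insects are dark filled ellipses (body ~ U(20, 70)
with per-pixel speckle) with random orientation and axis ratio, placed
by rejection sampling so boxes never overlap, and each ground-truth box
is the tight bound of the rasterized ellipse. The full major axis is
capped at one sixth of the image side, keeping every object in the
small-object regime. Default scene: 320 px canvas, 3–12 insects of
semi-axes 4–14 px, mirroring a 330-image training corpus in scale.

What it does *not* emulate: insect texture/appendages, specular glare,
debris, overlapping insect clusters, lens distortion, JPEG artifacts.
Tests passing on this generator therefore validate the *geometry and
arithmetic* of augmentation and evaluation — box transforms, counts,
determinism, metric values — not detector-level performance on real
trap photographs, which requires training a detector on real data.

The fake-detector model (`DetectionNoise`) perturbs ground truth with
independent misses, center/size jitter scaled by a fraction of box
size, and Poisson-distributed spurious boxes; TP confidences are
U(0.6, 1.0) and FP confidences U(0.1, 0.6), so confidence ranking is
informative. Unit jitter draws are consumed regardless of magnitude,
which makes a jitter sweep at fixed seed move each detection along a
fixed ray away from its ground truth — the evaluator's monotone
degradation with jitter is then a sharp property rather than a
statistical tendency.

## Problem sizes and determinism

The verification suites run at deliberately small rasters (64–96 px)
and moderate replication (330-image enrichment counts, 500 randomized
geometric oracle cases, 1,000 matcher-oracle instances, 10,000-draw
sampler and Bernoulli-rate checks): all checked properties are
resolution-independent, so small canvases lose no generality. All
randomness flows through explicit numpy Generators; identical seeds
give byte-identical datasets, manifests and metric reports.

## Known limitations

- Rotation's AABB re-annotation inflates boxes of strongly elongated
  objects at oblique angles (inherent to axis-aligned annotations).
- The boundary ring of a rotated raster blends the fill color slightly
  differently from other bilinear implementations; interiors agree
  exactly.
- Greedy matching is the detector-evaluation convention, not an optimal
  assignment; on adversarial overlaps they can differ.
- Confidence ties in matching are resolved by input order; this matters
  only for degenerate synthetic inputs.
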