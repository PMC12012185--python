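# Methods

This note documents the models, algorithms and parameter choices behind
`stomakit`, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

Maize stomatal density is estimated from nail-polish imprints of the
abaxial leaf surface, imaged at 10× (2448×1920 px frames), nine pictures
per plant. Counting is phrased as single-class bounding-box detection
("stoma"), followed by counting rules and a density computation. The
production detector for this problem is a trained two-stage CNN; this
package models everything *around* such a detector — data model, synthetic
benchmark, counting, density, evaluation, splitting — and supplies a
classical detector strong enough to exercise the full pipeline on
synthetic imprints. Training a network, and reproducing real-data scores
(hold-out AP near 99 %, count correlation r = 0.996 against manual
scoring), are out of scope: they require trained weights and the real
image corpus. The synthetic end-to-end thresholds (mAP50 ≥ 0.9, count
agreement r ≥ 0.95, ≥90 % exact per-image counts on clean images) are the
desk-scale stand-ins for those numbers.

## Coordinate and data model

Boxes are float pixel corners `(x_min, y_min, x_max, y_max)`, origin
top-left; the COCO `[x, y, w, h]` form exists only at the JSON boundary.
Boxes reaching past the frame are clipped to it at load time, so every
area computation downstream — in particular the visibility filter — sees
the visible extent. One category ("stoma"); detections carry a confidence
in [0, 1]; string image ids are encoded as COCO `file_name` stems because
strict COCO wants integer ids.

## Synthetic imprint generator

**Geometry.** Monocot stomata sit in parallel cell files. Scenes place
stomata on jittered horizontal rows (`file_spacing` 240 px full scale,
i.e. 8 files per frame), with per-file counts drawn by stochastic rounding
of `stomata_per_file` (default 7.5 → ≈60 stomata per frame, ≈105 mm⁻² at
the nominal calibration — within the range reported for maize abaxial
surfaces). Within a file, slots are evenly spaced with ±10 % jitter:
real files keep at least an interstomatal cell between neighbours, so
spacing is fairly regular and neighbours do not touch. Stoma length runs
along the file (140 ± 14 px full scale), width across it (48 ± 5 px),
orientation jitter ±8°; all normals are clipped at ±40 %. A bounded
rejection loop enforces pairwise ground-truth IoU ≤ 0.1 and raises on
infeasible densities.

**Rendering.** A stoma is two filled ellipse lobes (semi-axes L/4 × W/2 at
±L/4 along the axis) darker than background by 0.28, with a lighter pore
slit (+0.12) between them — the minimal dumbbell a matched-scale blob
detector can find. Background is a low-frequency Gaussian random field
(amplitude 0.04 around level 0.62) plus sensor noise. Ground-truth boxes
are the analytic tight extents of the two lobes, border-clipped; rendered
stoma pixels therefore lie inside their boxes by construction.

**Quality strata.** `default`: focus jitter only (σ ≤ 0.8 px bound);
`blur`: Gaussian PSF σ = 9 px (full scale), which strictly lowers image
variance and mean gradient; `artefact`: ≥1 air-bubble ring (dark annulus,
slightly brighter interior, radii 60–240 px full scale) plus extra noise.
The severity values are free parameters — real imprint datasets do not
come with quantified blur/artefact levels — and are exposed in the specs.

**Edge visibility.** By default every stoma lies fully in frame
(`edge_visibility = 1.0`). Rationale: the counting pipeline deliberately
drops stomata under ~50 % visibility, so if the generator produced
heavily clipped stomata, the ground-truth count would no longer be the
correct oracle for count-agreement checks — the filter would be *right*
to disagree with it. Border-clipped boxes are still fully supported
(lower `edge_visibility`, or clip at load) and the visibility rule is
unit-tested against constructed border cases.

**Reproducibility.** One master seed; image *i* uses
`PCG64(SeedSequence([seed, 2, i]))`, so subsets regenerate identically on
any platform. The manifest carries a nominal calibration of 0.345 µm/px
at full frame (typical for a 10× objective on a 2/3″ sensor), scaled
inversely for small frames; real data must supply a measured calibration —
the density module refuses to invent one.

**What it does not emulate.** Uneven illumination, imprint tearing,
subsidiary-cell texture, dicot (scattered) patterning, partial focus
gradients within one frame, stomatal aperture variation. Passing the
synthetic end-to-end checks shows the pipeline plumbing and the counting
rules are correct, not that the classical detector would survive real
micrographs.

## Baseline detector

A deterministic classical pipeline on the contrast-normalized, inverted
image (stomata respond positive):

1. **Anisotropic DoG pyramid.** At scale σ the band-pass is
   `G(σ, aspect·σ) − G(1.6σ, 1.6·aspect·σ)` (σ on the cross-file axis,
   `aspect` ≈ stoma length/width ≈ 2.9). Six geometric scales cover the
   expected width range (mean ± 2.5 sd)/3.2. Gaussian smoothing uses
   normalized convolution at the frame (dividing by the blurred frame
   indicator): zero padding would attenuate edge stomata and reflect
   padding mirrors them into ghost peaks.
2. **Peaks.** 3×5×5 local maxima over (scale, y, x) above
   `response_threshold` (0.25) of the image's peak response. Confidence is
   the peak response divided by the image maximum (per-image min–max onto
   [0, 1] with the admissible minimum at 0) — this is what makes a 50 %
   confidence cut meaningful for this backend.
3. **Box refinement.** Each scale-derived box (height 3.2σ, width
   aspect·3.2σ; the 3.2 calibrated once against the generator's default
   dumbbell) snaps to the connected dark component under its peak:
   threshold the smoothed darkness at {0.35, 0.5, 0.65}× the local peak
   (rising until the component separates from neighbours), close with a
   5×5 structure to bridge the pore slit, and take the component's
   bounding box. A lone near-square component is a single guard-cell lobe;
   it is merged with the nearest partner component across the slit.
   Components that are truncated by the search window, outside the
   admissible size range, or not elongated fall back to the coarse box.
   Duplicate candidates (multiple scales, per-lobe responses) refine to
   the same component and collapse in NMS.
4. **NMS.** Greedy by descending confidence (ties: x_min, then y_min);
   survivors pairwise below `nms_iou` (0.3). Subset of input, idempotent.

`DetectorConfig.matched(scene_spec)` derives the scale range and aspect
from a scene's stoma-size distribution — the detector is scaffolding whose
scales must match the structure it looks for, exactly as a trained
detector's anchors match its training data.

## Counting rules

Per image, in one pass, two strict cuts in fixed order: keep detections
with confidence **strictly greater** than 0.5; then compute the mean box
area of the survivors and keep boxes **strictly larger** than half that
mean. The mean is never pooled across images (stomatal size varies by
genotype and conditions) and is computed over confidence-passing
detections — the rule targets surviving predictions. With ≤1 detection
the filter is a no-op (one box cannot be smaller than half its own mean).
Consequences worth knowing: a border box at exactly half the size of
uniform full boxes stays marginally above the cutoff at any finite n
(the mean includes the small box itself) and is excluded exactly at
equality — the tests pin this boundary behaviour; raising the confidence
threshold can never increase a count.

## Density

`SD = mean(per-image counts) / image area [mm²]`, image area
`w·h·(µm/px)²·10⁻⁶`. Nine images per plant is the standard layout;
deviations warn but compute (imprint failures cost images in practice).
Genotype summaries report mean ± SE (sd/√n) of plant-level densities;
SE is NaN for n = 1.

## Evaluation

COCO-style, single class. Greedy matching in descending confidence; a
detection claims the unmatched ground truth of highest IoU if that IoU
≥ threshold (0.5), ties in confidence break by (x_min, y_min), ties in
IoU by ground-truth index. Ranking is pooled globally across images
(per-image AP averaging rejected); images with detections but no ground
truth contribute false positives only. AP is the mean of the precision
envelope at the 101 recall levels 0.00 … 1.00; with one class mAP50 is
that AP at IoU 0.5. The engine is verified two ways: against an
exhaustive confidence-threshold-sweep oracle (equal to 1e-12 on hundreds
of random micro-instances, and within 1e-3 on full pipeline output — the
tolerance a cross-tool comparison would use), and against hand-derived
worked cases. Ties in confidence between the fast path and the sweep
oracle are avoided in the property tests by sampling distinct
confidences; with exact ties the per-rank convention (each detection its
own operating point, stable sort) is the documented behaviour.

`counting_agreement` is plain product-moment correlation plus MAE on
paired per-image counts; it refuses zero-variance inputs and fewer than
three pairs.

## Stratified splitting

Strata are the three quality groups. Global split sizes are the
largest-remainder rounding of `fraction × n` — 250 images at 0.6/0.2/0.2
give exactly 150/50/50 for *any* stratum mix. Within that constraint,
each stratum allocates by largest remainder too: leftover units go to the
(stratum, split) cells with the largest fractional remainders among
splits that still have a global deficit, ties broken by split order
(train, val, test) then stratum order. Pure per-stratum rounding cannot
guarantee the global sizes (strata 84/83/83 would give 150/51/49); the
constrained form keeps the global sizes exact and every stratum within
one record of its proportional share. Records are shuffled per stratum
with a seeded PCG64 generator, so a split is byte-for-byte reproducible
from its seed. Degenerate strata (fewer records than split parts) warn
and allocate best-effort.

## Preprocessing

Resize to a fixed width (800 px default) preserves aspect; height rounds
half-away-from-zero for platform determinism, boxes scale by the single
float factor. Flips reflect boxes about the midline and are involutions.
Normalization statistics are pooled pixel mean/sd computed streaming over
the training split only (train/val/test leakage is the classic failure
here); a constant image set is an error. Flip probabilities during
training are configuration (default 0.5 each) — the training itself
happens outside this package, against the `TrainingConfig` schema
(learning rate, batch size, RoI heads, 10 000/15 000 steps).

## Problem sizes and runtimes

The test suite and `scripts/acceptance.py` run on quarter-scale frames
(612×480, `SceneSpec.small()`), where the full pipeline processes an
image in ~1 s; the end-to-end benchmark uses 30 clean images (~1 800
stomata), the annotation-volume check samples 252 full-scale scenes
(~15 000 boxes) without rendering. These sizes keep a complete run in a
few minutes on one CPU while leaving every measured quantity
seed-reproducible.

## Known limitations

* The classical detector is tuned to the generator's contrast polarity
  (dark stomata on light background) and degrades on the blur stratum by
  design; it is a backend stand-in, not a competitor to a trained CNN.
* The adaptive area filter assumes roughly unimodal stoma sizes per
  image; a genuinely bimodal size distribution would shift the mean and
  the cutoff.
* AP with zero ground truth and zero detections is defined here as 1.0
  (vacuous agreement); COCO tooling reports it as undefined.
* The density module treats the nine images of a plant as equal-area;
  mixed-magnification sampling within one plant is not supported.
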