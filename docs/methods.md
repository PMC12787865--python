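# Methods

## Model and assumptions

The pipeline estimates per-item food volume from a single overhead relative
depth raster plus binary segmentation masks. Three assumptions carry the
whole method:

1. **The plate rim is flat and food-free.** The annular band just inside the
   plate mask boundary samples the plate surface, so a plane fitted to it is
   the local "zero elevation" reference.
2. **The depth model's tilt artifact is planar.** Perspective-induced bias in
   monocular relative depth is modeled as a single global plane
   `z = a·x + b·y + c`; subtracting it removes the bias everywhere on the
   tray. Curvature in the artifact is not modeled.
3. **Corrected depth is proportional to physical height.** Summing the
   positive part of `z_corrected` over a mask, scaled by the pixel area
   `s²`, yields a volume in arbitrary units that is comparable across items
   and frames captured under the same conditions. Mapping a.u. to cm³ or
   grams requires per-food calibration and is handled by the density models,
   never assumed by the geometry.

Depth polarity (whether larger values mean higher elevation) is a
model-dependent convention, so it is carried explicitly on every `DepthMap`
and normalized to higher-is-elevated before correction. Flipping uses
`max(values) − v`, which preserves relief exactly; the absolute offset it
introduces is irrelevant because the base-plane subtraction removes any
constant.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `band_width` | 5 | px | rim annulus width; wide enough to average mask-edge noise, narrow enough to stay on the flat rim |
| `pixel_area` (`s²`) | 1.0 | arbitrary area | scales all volumes linearly; metric calibration is deliberately deferred |
| `polarity` | higher_is_elevated | – | matches the common convention of monocular depth models (nearer = larger) under an overhead camera |
| `max_rim_points` | 5000 | points | deterministic uniform stride (never RNG) bounds the least-squares cost |
| clip threshold | exactly 0 | depth | only strictly positive corrected values integrate; no epsilon margin |
| rank tolerance | 1e−10 | – | singular-value ratio below which the rim support is treated as collinear |

All floating-point accumulation is float64 regardless of raster storage
precision, because a volume is a sum of ~10³–10⁵ small terms.

## Numerical choices

* **Plane fit:** `numpy.linalg.lstsq` (SVD) rather than normal equations;
  rank deficiency raises a typed `DegeneratePlaneFitError` instead of
  returning garbage coefficients.
* **Rim band:** morphological erosion with the 4-connected structuring
  element iterated `band_width` times; band pixels are emitted in row-major
  order so downstream results are order-independent and reproducible.
* **ROI resampling:** bilinear interpolation with *linear extrapolation* at
  the borders (scipy `RegularGridInterpolator`, pixel-center aligned).
  Edge-clamping resizers bend planar rasters in the outermost rows, which
  would leak tilt into the corrected map; with extrapolation a planar raster
  survives any downsample/upsample chain to < 1e−6, so plane correction
  commutes with ROI resampling on plane-only scenes.
* **Degenerate inputs:** empty food masks yield zero-volume estimates with a
  warning (one bad mask must not abort a multi-item frame); a missing tray
  or an unusable rim marks the frame failed with a typed reason, and failed
  frames are excluded from statistics but counted in the report.
* **Tie-breaks:** tray selection takes the highest-confidence detection,
  ties broken by larger box area; the mock segmenter matches prompts to
  items by bounding-box IoU, so a tight prompt beats a containing box.

## Synthetic scenes: what they emulate and what they do not

The generator reproduces the *geometric* structure of an overhead tray
capture: a planar tilt over the whole grid (coefficients up to
|a|, |b| = 0.1 per pixel, a deliberately harsher tilt than a depth model
typically produces), a flat circular plate with a food-free rim, food items
as solids with closed-form volumes (spherical cap πh²(R − h/3), cone
⅓πr²h, box w·l·h) rasterized at pixel centers, i.i.d. Gaussian depth noise
(default sd 0.005, i.e. 0.5 % of the nominal depth range), and rotation
sequences of the same items. Depth units are tied to pixel units so analytic
volumes are in pixel³ — the same arbitrary units the integrator reports.

It does **not** emulate texture-dependent depth-model failures, segmentation
boundary errors, specular highlights, occlusion, or motion blur. Passing
tests therefore demonstrate that the *geometric* stages — rim fit,
correction, integration, statistics — are correct and tilt-invariant; they
do not certify accuracy on real cafeteria imagery, which additionally
depends on the perception backends' quality.

Items may not overlap (an error), since overlap would make per-item ground
truth ambiguous. Rotation sequences rotate every item by the block angle;
ground-truth volumes are invariant across a sequence by construction.

## Density calibration

The physical premise is constant density per food class, so the default
model is proportional through the origin, `w = k·V`, with the closed form
`k = Σ wV / Σ V²`; an affine variant is available for foods whose served
portions carry a fixed offset. Predictions are floored at 0 g. The error
metric for held-out evaluation is mean absolute percent error; with 20
training pairs under 5 % multiplicative noise the factor `k` is recovered
within 2 % and held-out MAPE stays below 6 %.

## Statistics

Per rotation block: mean, sample SD (n − 1 denominator — per-pass frame
counts are small), and CV = 100·SD/mean. The pooled CV is computed over the
concatenation of all frames, never over block means, so within-pass
fluctuation is not averaged away. Both SD (a.u.) and CV (%) are emitted in
reports, covering either reading of "spread" a consumer may want.

## Problem sizes

Scenes are rendered at 512×512 for volume-recovery and rotation experiments
(with 128/256/512 used for the resolution-convergence check), 20 noise seeds
per rotation for the noisy-CV experiment, and 20 calibration pairs per fit.
These sizes keep the full validation run fast on a single CPU while leaving
rasterization error well below the effects being measured.

## Known limitations

* Volumes are relative; without density calibration no metric claim is made.
* A curved (non-planar) depth artifact, or food covering the entire rim,
  breaks the base-plane assumption; the latter is detected and reported
  ("rim unavailable"), the former is not detectable from a single frame.
* The mock backend returns ground-truth masks; real segmentation error is
  out of scope of the shipped backends.
* `normalize_polarity` uses the raster's own maximum as the flip pivot,
  which is exact for full-tray rasters but means two crops of the same
  frame can differ by a constant (harmless after plane subtraction).
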