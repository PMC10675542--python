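# Methods

## Problem setting

Slide scanners segment tissue on a low-resolution preview photograph of
the whole glass slide to decide where to scan and focus. A segmentation
model trained mostly on clean slides misreads imaging artifacts — felt-pen
ink on the glass, air bubbles in the covering glue, dirt, manufacturer
brand marks — either as tissue (wasting scan time and ruining focus) or,
worse, suppresses real tissue that resembles an artifact. `slideaug`
manufactures training examples of artifact-bearing slides from two assets
a lab already has: clean annotated previews, and a handful of slides whose
artifacts have been hand-labeled once.

## The compositing model

Brightfield imaging is multiplicative in transmitted light: a translucent
artifact between lamp and camera can only make pixels darker. We
approximate stacking in 8-bit intensity space with a subtractive blend.
Writing `S = 255 − I_over` for the artifact's *strength* (its negative),

    I_out = max(0, I_in − S) = max(0, I_in + I_over − 255)

per pixel and channel. Two consequences the implementation and tests lean
on:

* **Identity outside the artifact.** Overlays are stored in canonical
  white-background form (255 at every pixel outside the artifact mask), so
  the blend needs no conditional: `S = 0` there and the preview passes
  through bit-exactly. This is equivalent to masking the negative overlay
  to zero at background.
* **Monotonicity.** `I_out ≤ min(I_in, I_over)` pointwise: augmentation
  never brightens a pixel, and the darker of tissue and artifact always
  survives — a felt-pen stroke over tissue looks like ink *over* tissue.

The blend is computed vectorized in int16 (no unsigned wraparound); a
per-pixel triple-loop oracle in the test suite pins it bit-exactly.

Saturation at 0 makes the blend slightly lossy for very dark pixel/overlay
pairs (true optical stacking would be multiplicative); at preview
brightness levels the clamp is rarely active and the approximation is the
point of the method, not a defect of the implementation.

### Placement

Each axis is handled independently. An overlay narrower (shorter) than the
preview receives a uniform integer offset `x0 ∈ [0, N − w]`
(`y0 ∈ [0, M − h]`); one wider (taller) is placed at offset 0 and a
uniform crop window start `crop_x ∈ [0, w − N]` (`crop_y ∈ [0, h − M]`)
selects which part of the overlay is used. Every size combination
therefore has a valid placement, including overlays wider but shorter than
the preview. Crop starts are drawn uniformly because nothing favors any
window.

### The segmentation label

The tissue mask passes through augmentation unchanged. Artifacts are
*background* for the tissue-detection task: the model must learn to keep
detecting tissue under and around them, not to segment the artifacts
themselves. Pipelines that want artifact labels can use the emitted
per-overlay footprint masks.

## Overlay transformations

Applied in the fixed order scale → rotate → mirror → hue → scratch →
Perlin fade → intensity. The transformations are mutually independent; the
fixed order exists so that a parameter record replays bit-exactly. The
first three are geometric and apply to every category; the last four are
content transforms restricted to felt-pen overlays (other artifact types
have physically fixed appearance — a bubble's rim does not change hue).

| transform | parameter, default sampling | notes |
|---|---|---|
| scaling | factor ~ U[0.75, 1.25] | dims = ⌊d·f + 0.5⌋, min 1; bilinear patch, nearest mask |
| rotation | integer angle ~ U{0..359} | canvas expands to the rotated bounding box; multiples of 90° are exact index permutations |
| mirroring | axis ~ U{horizontal, vertical, both, none} | exact involutions |
| hue | integer ~ U{0..180} (half-degree HSV units) | replaces H of masked pixels; S, V preserved within 1 level |
| scratch | count ~ U{1..10}, factor f ~ U[0, 0.2] | 1-px lines between two distinct random edges; strength ×= 3×3-box-blurred factor map where the lines cross the mask |
| Perlin fade | weight ~ U[0, 1]; cells 4, normalize on, no threshold | strength ×= (1 − weight·noise), noise ∈ [0, 1] |
| intensity | factor = √u, u ~ U[0.3, 0.7] | strength ×= factor, i.e. patch' = 255 − f·(255 − patch) |

Numerical choices worth stating:

* **Strength space for content transforms.** A scratch scrapes ink off the
  glass and lets light through; fading and intensity scaling likewise make
  the artifact *fainter*. All three therefore attenuate strength
  (`S' ≤ S` pointwise, enforced by tests), never darken the patch. The
  sentence-level alternative (scaling the patch itself) would make scratch
  lines darker than the ink, which is physically backwards.
* **Scratch weight map.** The map holds each line's factor on its pixels
  and 0 elsewhere and is blurred with a 3×3 mean kernel; strength is
  multiplied by the blurred factor on the blur-widened line support
  intersected with the mask. A factor of 0 therefore erases the strength
  on the line core entirely (intensity 255), with soft shoulders from the
  blur. The factor is one draw per chain, applied to every line — a
  "constant per line" choice that keeps the parameter record a single
  scalar.
* **Sub-seeds.** Scratch-line geometry and the Perlin field are random
  but must be replayable from a parameter record alone, so `sample_params`
  draws two 31-bit sub-seeds into the record. With them, `apply_chain` is
  a pure function of (overlay, params).
* **Rotation fill.** Raw rotation fills exposed corners with a constant,
  but the composition is mask-gated, so the fill value is unreachable; the
  canonical form re-whitens everything outside the rotated
  (nearest-neighbour) mask. Masks are re-binarized after every geometric
  op so no gray mask levels appear.
* **Hue convention.** [0, 180] in half-degree units (the common 8-bit HSV
  convention); 180 wraps to 0. Pixels with zero saturation have no defined
  hue and come back unchanged.
* **Gradient noise.** The Perlin field is classic lattice gradient noise
  with quintic fade, written in-package (it is a ~60-line primitive that
  the fading transform is defined in terms of). The `cells` parameter is
  the number of noise cells across the patch; 4 gives blob-scale fading on
  typical overlay crops.
* **Degenerate sizes.** Extreme downscaling or thin-mask rotation can
  leave the nearest-neighbour mask empty; the overlay invariant (≥ 1
  foreground pixel) is preserved by re-marking the centre pixel. This only
  triggers on pathological inputs (1–2 px artifacts).

## Artifact bank

Extraction splits the hand-labeled mask into 8-connected components
(4-connectivity would fragment thin diagonal pen strokes), drops
components below `min_area` (default 9 px — labeling specks), and crops
each to its bounding box plus a 2-px margin so the scratch transform's
3×3 blur never touches a crop border. Within a crop, pixels of *other*
components are whitened, so summed component areas conserve the labeled
foreground exactly. Whole-mask extraction (all components in one overlay)
is available for artifacts whose parts belong together. Banks persist as
per-overlay PNG pairs plus a JSON manifest.

## Pipeline

`prepare` resizes annotated previews to a fixed working resolution
(default 512 rows × 1024 columns — preview slides are landscape) with a
bilinear image / nearest-binarized mask and splits ids 80:20
(train = ⌊0.8·n⌋) after a seeded shuffle. `augment` co-emits each original
with its augmented copies: the archive's clean slides remain in the
training set, augmentation extends it. Per-sample streams are seeded by
`sha256(master_seed, sample_id, copy_index)`, so a rerun — or a reordered,
parallel run — reproduces every output byte-for-byte (uncompressed
baseline multi-page TIFF, deterministic PNG; verified by tree comparison
in the tests).

Per-category transform toggles, sampling ranges, the overlay count
distribution (default U{1..3}), category mix weights and per-sample-type
exclusion rules (e.g. no felt pen on smear slides) live in one YAML
config whose defaults reproduce the published sampling ranges.

## Metrics

Sensitivity `TP/(TP+FN)`, precision `TP/(TP+FP)`,
F1 `2TP/(2TP+FP+FN)` and IoU `TP/(TP+FP+FN)` over pixel confusion counts,
with foreground positive. A zero denominator yields 0 by default (the
worst-case convention; an `empty_value` flag scores two empty masks as 1
instead). Per-category evaluation averages per-image metrics and reports
the population standard deviation (a sample-std flag exists); pooled-pixel
aggregation is available as an alternative. The algebraic identities
F1 = 2·IoU/(1+IoU) and F1 = harmonic mean(sensitivity, precision) are
property-tested.

## Synthetic fixtures

Real preview archives are proprietary, so the fixture generator emulates
their structure: a near-white field with smooth gradient-noise texture, a
darker label area on the left (configurable fraction of the width), and
1–4 tissue blobs — ellipses with a low-order random-Fourier radial wobble
— filled with stain-like color (eosin-pink or hematoxylin-purple) plus
per-pixel jitter. The tissue mask is by construction exactly the painted
support. Synthetic artifacts per category: saturated thick Bezier strokes
(felt pen), a bright disk with darker rim (bubble), scattered dark
speckles (dirt), dark rectangles (brand mark).

What the fixtures do **not** emulate: real stain texture and nuclear
detail, real artifact appearance (bubble refraction rings, ink
granularity), camera noise, vignetting, or slide-to-slide illumination
drift. Passing tests therefore certify the *algebraic and statistical
contracts* of the method — blend exactness, footprint confinement,
parameter-range and placement-law conformance, determinism — not that
training on augmented synthetic previews improves a real detector. That
claim needs a real archive and a trained segmentation model, both outside
this package's scope (the package emits standard image/mask pairs any
trainer can consume).

Problem sizes used by the default test run and `scripts/acceptance.py` —
96×192 to 256×512 fixture previews, 12–20-sample datasets, 32–64 px
overlays, 100-trial oracle comparisons, 10,000-draw statistical checks —
were chosen so the whole suite runs in well under a minute while leaving
the statistical assertions (3σ binomial bands) sharp.

## Known limitations

* The subtractive blend clamps at 0 instead of compounding
  multiplicatively; stacked dark artifacts saturate.
* Scratch lines are straight and one pixel wide pre-blur; real scratches
  curve and vary in width.
* Bubble overlays occlude like any other artifact; real bubbles refract
  and can *brighten* edges, which a subtractive model cannot produce.
* `evaluate` assumes per-image metric averaging when reproducing
  table-style reports; pooled-pixel numbers differ on heterogeneous image
  sizes.
* The U-Net (or any) segmentation model itself is out of scope: this
  package prepares data and scores predictions, it does not train.
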