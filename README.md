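# slideaug

Copy–paste **artifact overlay augmentation** for microscope-scanner slide
preview images.

Whole-slide-image scanners photograph each glass slide at low resolution
(a few megapixels) before scanning and segment the tissue on that preview
to plan the scan path and focus points. Segmentation models trained on
clean slides fail on slides carrying imaging artifacts — felt-pen markings,
air bubbles trapped in the covering glue, dirt speckles, brand marks —
because such slides are rare in training archives. `slideaug` synthesizes
them: it extracts labeled artifact instances from faulty slides into a
reusable bank, diversifies them with seven parameterized transformations,
and composites them onto clean annotated previews, producing augmented
image/mask training pairs for any segmentation architecture. It also ships
the standard pixel metrics (sensitivity, precision, F1, IoU) used to
validate tissue detectors per artifact category.

## The method

Brightfield images multiply transmitted light, so an artifact is added to
a preview by subtracting the artifact's *negative* from it. With the
overlay patch `I_over` stored in canonical white-background form (255
outside the artifact mask), the blend is

```
I_out(x, y, c) = max(0, I_in(x, y, c) + I_over(x̃, ỹ, c) − 255)
```

per pixel and RGB channel. Outside the artifact the blend is an identity;
inside it the darker of preview and overlay always wins, so tissue under a
translucent marking stays visible, exactly as on a real marked slide. The
ground-truth tissue mask is *not* modified — the detector learns to find
tissue despite artifacts.

Before placement each overlay is diversified by up to seven seeded
transformations: **scaling** (factor ∈ [0.75, 1.25]), **rotation**
(integer angle ∈ [0°, 359°], canvas expanded), **mirroring**
(horizontal/vertical/both), and — for felt-pen overlays only — **hue
replacement** (random hue ∈ [0, 180] in half-degree HSV units, saturation
and value preserved), **scratches** (one-pixel lines between image edges,
attenuation factor ∈ [0, 0.2], 3×3-blurred), **Perlin-noise fading**, and
**intensity scaling** (factor √u, u ∈ [0.3, 0.7]). Placement offsets are
uniform over the valid range; overlays larger than the preview are cropped
by a uniform random window.

## Worked example

```python
import numpy as np
from slideaug import (AugmentationConfig, FixtureSpec, BankSpec,
                      augment_sample, generate_bank, generate_clean_preview)

preview = generate_clean_preview(FixtureSpec(height=256, width=512,
                                             blob_radius=(20, 50), seed=7))
bank = generate_bank(BankSpec(dims=(64, 64)), seed=1)
cfg = AugmentationConfig(overlay_count=(2, 3))

out, records, footprints = augment_sample(preview, bank, cfg,
                                          np.random.default_rng(42))
for r in records:
    print(r.category, r.params.rotation_angle, (r.placement.x0, r.placement.y0))
changed = (out.image != preview.image).any(axis=2)
print("changed pixel fraction:", round(changed.mean(), 4))
print("tissue mask unchanged:", np.array_equal(out.tissue_mask,
                                               preview.tissue_mask))
```

prints

```
bubble 30 (82, 14)
brand_mark 274 (55, 150)
changed pixel fraction: 0.031
tissue mask unchanged: True
```

Two artifacts (an air bubble rotated by 30° placed at column 82 / row 14,
and a brand mark rotated by 274° at column 55 / row 150) were composited;
they touched 3.1 % of the pixels, and the segmentation label was left
untouched. Each record is sufficient to replay its augmentation
bit-exactly (`slideaug.replay_records`).

The same workflow from the shell:

```sh
slideaug generate-fixtures --count 10 --seed 1 --out fixtures/
slideaug augment --input-dir fixtures/previews --bank-dir fixtures/bank \
    --seed 42 --copies 2 --out augmented/
slideaug evaluate --pred-dir preds/ --truth-dir truths/ \
    --manifest categories.csv --out report
```

`extract` builds a bank from your own labeled two-page annotation TIFFs
(page 1 = preview, page 2 = white-on-black artifact mask), and `prepare`
resizes a dataset to a fixed working resolution (default 512×1024) and
splits it 80:20 into training and validation ids.

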