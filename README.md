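# ryeview

Ensemble top-view image segmentation and growth-trait extraction for
field-grown spaced perennial-ryegrass (*Lolium perenne*) plants.

## The problem

Phenotyping (re)growth of individual grass plants in the field means
segmenting one green, thin-leaved tuft from brown soil in thousands of
top-view photographs taken across two growing seasons — under changing
light, white balance, soil moisture, algae cover and post-cut leaf
discolouration. No single segmentation rule survives all of that; an
ensemble does.

`ryeview` implements that ensemble pipeline:

1. **Eight segmentation operators**:
   - `C1` — HSV colour windows H ∈ [35, 100], S ∈ [50, 255], V ∈ [40, 226]
     (8-bit channels);
   - `C2` — blue/green ratio B/G < 0.625;
   - `T1` — FFT low-pass (raised-cosine, radius 25 frequency px) of the
     saturation channel, threshold 110;
   - `T2` — local Shannon entropy (100 × 100 window) of the saturation
     channel, threshold 4.7 bits;
   - `E1`–`E4` — Prewitt-family edge operators (gradient magnitude L2 > 29;
     centre-weighted 3×3 convolution ÷13 ≥ 230; gradient L1 > 27;
     thresholded-and-thinned edges > 15), each after 5 × 5 Gaussian
     smoothing.

   Every raw mask is cleaned by dilate → fill holes → erode → keep the
   largest connected object.

2. **Majority-vote fusion**: a pixel belongs to the plant iff at least
   4 of the 8 masks contain it (equivalently, a weighted composite at
   256/8 intensity per mask thresholded at 128); the largest object is the
   detection.

3. **Agreement evaluation**: precision P, recall R and F = 2PR/(P+R) for
   any mask pair; the 28-pair (8·7/2) mean-F agreement matrix over an
   image set; per-method scores against a reference mask.

4. **Growth traits**: pixel areas → cm² via the pixels-per-cm scale;
   thermal time Σ max(0, (T_min+T_max)/2 − T_base) with T_base = 0 °C;
   *base area* (W0, directly after a cut), *regrowth*
   (W1 − W0, optionally per °C·day) and *first-year lateral expansion*
   (OLS slope of W0 area vs cumulative thermal time, ≥ 3 valid
   observations); genotype means over clonal replicates and Pearson
   correlation against manual measurements (tiller counts, leaf growth).

Because real field archives of this kind are not public, the package ships a
seeded **synthetic scene generator** that emulates the imaging conditions
(dense leaf tufts on textured soil, algae, weeds, illumination and
white-balance drift) with exact ground-truth masks, plus growth-series and
temperature generators, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from ryeview import (SceneParams, generate_scene, SegmentationConfig,
                     segment_all, composite_vote, precision_recall_f,
                     pixels_to_area)

scene = generate_scene(SceneParams(seed=1))          # 512x512 px, 18.59 px/cm
cfg = SegmentationConfig.for_scale(scene.params.pixels_per_cm)
masks = segment_all(scene.image, cfg)                # the 8 cleaned masks
det = composite_vote(masks)                          # >= 4-of-8 fusion

score = precision_recall_f(det.composite, scene.truth)
print(f"true area  {scene.true_area_cm2:.1f} cm^2")
print(f"detected   {pixels_to_area(det.area_px, scene.params.pixels_per_cm):.1f} cm^2")
print(f"P={score.precision:.3f} R={score.recall:.3f} F={score.f_value:.3f}")
```

prints

```
true area  73.8 cm^2
detected   84.0 cm^2
P=0.878 R=1.000 F=0.935
```

The composite recovers the full tuft (recall 1.0) with a thin halo of
soil pixels around the leaves (precision 0.88) — at this reduced scale the
edge operators' ~2 px support is a visible fraction of a leaf's width, so
detected areas run a few percent above truth.

## Command line

```bash
ryeview synth --n-scenes 10 --seed 3 --out scenes/      # test suite with truth
ryeview segment scenes/G001_1_Y1C2_W0.png --out masks/  # 8 masks + composite + overlay
ryeview batch scenes/ --out run/ --pixels-per-cm 18.59  # detections.csv + summaries
ryeview evaluate masks/ --out eval/                     # 28-pair agreement, P/R/F tables
ryeview traits run/detections.csv temps.csv cuts.csv --out traits/
```

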