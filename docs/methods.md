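# Methods

## The pipeline

`ryeview` segments one spaced perennial-ryegrass plant per top-view RGB
frame and turns the detected areas into growth traits. The design premise
is that no single segmentation rule is robust across field conditions
(light spectral quality and intensity, soil moisture and texture, algae
and weeds, post-cut leaf yellowing), but a committee of complementary
rules is: each of eight operators votes per pixel, and a pixel is plant
iff at least four agree.

### Segmentation operators

All operators except `C2` work in HSV space with every channel scaled to
[0, 255]; hue maps degrees × 255/360 and is rounded half up, with hue 0
assigned to achromatic pixels. The texture and edge operators use the
saturation channel, which separates vegetation from soil most strongly.

| op | principle | parameters (defaults) |
|----|-----------|------------------------|
| C1 | colour windows | H ∈ [35,100], S ∈ [50,255], V ∈ [40,226], inclusive |
| C2 | blue/green ratio | B/G < 0.625; G = 0 pixels → background |
| T1 | frequency-domain low-pass | raised cosine, unit DC gain, half amplitude at radius 25 frequency px, zero at 50; output > 110 |
| T2 | local entropy | 256-bin Shannon entropy, 100 × 100 window, reflect padding; > 4.7 bits |
| E1 | Prewitt gradient magnitude (L2) | > 29 after 5×5 Gaussian (σ = 1) |
| E2 | centre-weighted 3×3 convolution | centre 15, others 1, ÷ 13, clipped to [0,255]; ≥ 230 |
| E3 | Prewitt gradient (L1) | > 27 after the same smoothing |
| E4 | thresholded, thinned edges | L2 gradient > 15, morphological thinning, ≥ 1 |

Threshold semantics: window bounds are inclusive; scalar thresholds are
strict (`> t`), except E2 where clipping makes 255 a mass point and the
comparison is `≥`. E1 and E3 are deliberately differentiated by their
gradient norm (L2 vs L1): they are described identically up to the norm
but behave as distinct, highly-correlated operators, which matches their
observed near-but-not-complete agreement in the field. E4's
"refine edges" semantics are realised as threshold-then-thin; the original
operator's internals are proprietary, so this is an explicit approximation
isolated behind the operator boundary, as are T1's cosine filter and the
exact gradient conventions.

Every raw mask passes the same cleanup: dilation with a disk structuring
element, hole filling (4-connected background), erosion with the same
disk, selection of the largest 8-connected component (ties broken by
first pixel in row-major order). The disk radius is 5 px at the reference
optics of 74.36 px/cm and scales proportionally with resolution
(`SegmentationConfig.for_scale`), with a floor of 1 px. Note that a dilate–erode closing can only add
pixels, so it cannot itself remove small spurious objects; it is the
largest-object step that discards them. For the edge operators the cleanup is what converts a
closed edge *ring* into a filled object.

### Composite fusion

Votes are counted as integers and thresholded at ≥ 4 of 8. This is exactly
the weighted-intensity formulation (each mask contributing
256/8 = 32 of a 255-maximum image, thresholded at 128: 4 × 32 = 128)
without 8-bit rounding ambiguity; the equivalence is enumerated
exhaustively over all 2⁸ membership patterns in the test suite. After
thresholding, only the largest component is kept and its boundary is the
red outline overlay.

Human visual inspection of each detection is replaced by an automated
criterion: with ground truth available, a detection is correct iff
IoU ≥ 0.8; without, a heuristic flags empty detections, detections
touching > 25 % of the frame border, or covering > 60 % of the frame.
These thresholds are artifact choices, exposed in the API.

### Evaluation

P = |pred ∩ ref| / |pred|, R = |pred ∩ ref| / |ref|, F = 2PR/(P+R),
with the 0/0 → 0 convention (an empty prediction or reference scores 0
and the image is counted; callers can drop such images instead, matching
the field practice of excluding incorrectly analysed frames). F is
invariant to which mask acts as reference, so method agreement uses each
unordered pair once: 8 methods → 28 comparisons per image, averaged over
images into the agreement matrix. Per-method scores against a reference
report mean and standard error (sample SD/√n over scored images).

### Traits

* `pixels_to_area`: count / (px-per-cm)².
* Thermal time: Σ max(0, (T_min + T_max)/2 − T_base), T_base = 0 °C —
  the standard GDD formulation from daily extremes.
* Regrowth: W1 − W0 area for the same plant and cut; negative values are
  retained and flagged (cut damage and segmentation noise are real).
* First-year lateral expansion: OLS slope of W0 area against cumulative
  thermal time; undefined below three valid observations (no exception,
  a flagged no-estimate result).
* Genotype values are means over the available valid clonal replicates;
  a genotype with none is excluded. Correlations (Pearson r, two-sided p)
  are computed on genotype means with pairwise-complete deletion; no
  multiple-testing correction is applied.
* Leaf growth divides the 2-week plant height by the thermal time of that
  cut's 2-week window (the per-cut window; a per-plant window is not
  distinguishable in the data layout).

## The synthetic study conditions

No real field archive ships with the package, so the generator
emulates the imaging conditions with exact ground truth. Its defaults
*are* the study conditions for all end-to-end tests; they were chosen
once, from the morphology and climate of the emulated trial, and are not
tuning knobs:

* **Frame and scale**: 512 × 512 px at 74.36/4 ≈ 18.6 px/cm — the
  reference field optics downsampled 4× with a plant-centred crop, keeping the
  test suite desk-sized.
* **Plant**: 120 curved, blunt-cut leaf stubs (taper 0.3) of
  4.5 ± 1.0 cm × 0.55 ± 0.1 cm radiating from the centre — a dense
  stubble tuft, as a freshly cut plant of some hundred tillers presents
  from above. Foliage hue sits at H8 45–95 (inside the colour window),
  S8 140–220, V8 100–200, with continuous per-pixel shading grain.
* **Soil**: brown base (112, 96, 80) with multi-octave luminance texture,
  a moisture gradient across the frame, and spatially smooth chroma noise
  (camera demosaicing leaves chroma far smoother than luminance).
* **Nuisance structure**: algae patches sharing the foliage hue but with
  a fine texture scale (exercising the colour/texture complementarity),
  and small weed speckles. Both are placed outside the weeded tuft
  footprint — in a maintained trial algae forms on open moist soil, not
  under the plant canopy — and both are background in the ground truth.
  Optional brown leaf sectors emulate post-cut yellowing.
* **Lighting**: global gain (nominal 0.7–1.3) and per-channel
  white-balance factors, applied after drawing, so ground truth is
  lighting-invariant.
* **Growth series**: W0 base areas follow `base + slope × GDD` with
  Gaussian noise (floored at 5 cm²); defaults slope
  0.059 cm² °C⁻¹ day⁻¹ (a representative field mean), base 40 cm², cuts at
  0/650/1300/1950 °C·day (6-week intervals at a ~15 °C mean) and a
  one-week regrowth window of 90 °C·day. Scene sizes are solved to each
  target area within 5 % by scaling tiller count (∝ s^0.8) and leaf
  dimensions (∝ s^0.6) — larger plants are denser tufts, as in reality.
* **Temperatures**: seasonal sinusoid plus weather noise, with the daily
  mean of (tmin, tmax) kept exactly on the profile.

What the generator does **not** model: photorealistic optics (flash
geometry, vignetting, lens distortion), occluding neighbours, 3-D canopy
structure, JPEG artefacts, or soil that genuinely percolates into the
tuft. Passing the synthetic suite therefore shows the machinery is
correct and robust across the modelled variation; it does not certify
field success rates on real images.

## Numerical choices and known limitations

* Gaussian smoothing uses σ = 1.0 for the 5 × 5 kernel, normalised to
  sum 1, reflect padding (mean-preserving).
* The exact entropy path uses a sliding-histogram rank filter on a
  reflect-padded frame; a strided path (per-bin integral images evaluated
  on a stride-k grid, nearest-neighbour upsampled) is available behind
  `entropy_stride` for speed, default exact.
* T2's 100 × 100 window and T1's radius-25 filter keep their
  field-calibrated pixel-scale defaults. At the reduced synthetic scale the entropy window
  spans ~5 cm, so T2 produces a plant-plus-halo blob (high recall, low
  precision) rather than a tight mask; it still contributes useful votes
  and the composite is unaffected. The same scale effect gives the edge
  operators a ~2 px halo that is a visible fraction of a leaf's width, so
  composite areas at 18.6 px/cm run a few percent above ground truth and
  recovered expansion slopes inherit a bias of about +5 %; at the full
  74 px/cm field resolution both effects are negligible.
* Operator failures inside a batch never abort it: the method's mask is
  recorded empty and the failure logged; unreadable images yield a
  `failed` row. The pipeline itself uses no randomness; all stochasticity
  lives in the generators and is seed-determined.
* The slope-recovery experiment (4 cuts, W0 noise sd = 10 % of the series
  mean area) operates near its statistical limit by construction: the
  per-genotype OLS slope standard error is ~11 % of the programmed slope,
  so the median relative error over 50 genotypes sits around 8 % and
  individual genotypes can exceed 20 %. This is a property of the design
  (4 points, strong noise), not of the implementation.
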