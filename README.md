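# pollensep

Separation and classification of overlapping pollen grains in stained
light-microscopy images.

Automated airborne-pollen monitoring (allergy calendars, climate and
forensic studies) needs to count and identify grains on slide
photographs. The hard part is that grains often lie on top of one
another: a plain segmentation merges a clump into one blob and
undercounts. `pollensep` implements an end-to-end pipeline that detects
those clumps, splits them into individual grains, and evaluates
12-species classification — for palynologists and image-analysis
researchers who want a reproducible, fully testable reference
implementation that runs without any external dataset.

## Method

1. **Preprocess** — sRGB → CIELAB; segmentation works on the
   chromaticity vector x = [a\*, b\*] only (the purple stain is a
   chromatic signature).
2. **Segment** — mean shift with a flat kernel of bandwidth h = 25
   reduces the scene to a few color modes; Otsu's threshold on the mode
   image's a\* values yields the pollen mask (foreground = higher mean
   a\*), holes filled, debris removed.
3. **Case decision** — each region is eroded by disks with Fibonacci
   radii F₁…F₂₁ = 0, 1, 1, 2, 3, …, 6765. A single convex grain keeps
   one object until it vanishes (**Case I**); a clump pinches apart
   first, so the object count near the end differs from the start
   (**Case II**).
4. **Separate** — for Case II, the split fragments are dilated back
   into per-grain seeds (stopping before they touch), and each seed
   drives a gradient-vector-flow (GVF) active contour
   (x(s) = [x(s), y(s)], s ∈ [0, 1]) toward the region boundary; the
   contours partition the region into one mask per grain.
5. **Describe** — each grain yields 33 features: 6 shape (MA, mA, A, P,
   R = 4πA/P², C = A/P²), 5 first-order statistics (μ, m, σ², σ,
   entropy S) per Lab channel, and 4 Haralick co-occurrence statistics
   (contrast, correlation, energy, homogeneity) per Lab channel.
6. **Classify** — multilayer perceptron, random-tree forest and naive
   Bayes under stratified s-fold cross validation (s = 2, 5, 10);
   per-class and support-weighted TPR/PPV/FPR/F1 from the pooled
   confusion matrix.

A seeded synthetic-scene generator (purple elliptical grains with exine
rings and texture noise, pale cluttered background, exact ground-truth
masks) makes every stage testable offline. See `docs/methods.md` for
the full model, parameter and design documentation.

## Worked example

Generate a scene with two overlapping grains and run the pipeline:

```python
import numpy as np
from pollensep import sample_scene, render_scene, process_image

spec = sample_scene(seed=2, n_grains=2, p_overlap=1.0)
rgb, truth_masks, cases = render_scene(spec)
report = process_image(rgb)

region = report.regions[0]
print("color modes found:", report.n_modes)
print("region case:", region["case"])
print("erosion counts:", [c for _, c in region["erosion_counts"]][:9], "...")
print("grains recovered:", len(report.grains))
vec = report.grains[0].features.as_array()
print("descriptor length:", vec.shape[0])
print("shape features (MA, mA, A, P, R, C):", np.round(vec[:6], 3))
```

```
color modes found: 2
region case: CASE_II
erosion counts: [1, 1, 1, 1, 1, 1, 2, 2, 0] ...
grains recovered: 2
descriptor length: 33
shape features (MA, mA, A, P, R, C): [3.60000e+01 3.50000e+01 9.92000e+02 1.15154e+02 9.40000e-01 7.50000e-02]
```

Reading the output: mean shift found 2 color modes (stain vs
background); the single connected region kept 1 object at small erosion
radii but split into 2 at radii 8–13 before vanishing — final count ≠
initial count, hence Case II; the snake separation recovered 2 grains.
The first grain's descriptor is 33 values; its bounding box is
36×35 px, area 992 px, traced perimeter 115.2 px, roundness 0.94
(near-circular) and compactness R/(4π) ≈ 0.075.

The same stages are scriptable from the shell:

```sh
pollensep synth --seed 42 --scenes 5 --out-dir scenes/
pollensep run scenes/scene_000.png --out report.json
pollensep evaluate --features grains.arff --learner mlp --folds 2 --seed 7 --out metrics.json
```

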