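# Methods

`pollensep` implements a complete pipeline for detecting, separating and
classifying pollen grains in stained light-microscopy slide images. This
note records the model behind each stage, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Problem setting

Airborne pollen sampled onto glycerin-jelly slides and stained (methyl
green) appears under the light microscope as purple, roughly elliptical
grains of 10–60 µm equivalent diameter on a pale, cluttered background
(mounting-medium smears, debris). Grains occur either isolated
(**Case I**) or in overlapping clumps (**Case II**); the clumps are what
make automated counting and species classification hard, because a naive
connected-component analysis undercounts them.

## Segmentation: mean shift on chromaticity + Otsu

Images are converted from 8-bit sRGB (D65 white point assumed; the
acquisition camera's primaries are unknown, and sRGB is the interchange
default) to CIELAB. Each pixel is represented by its chromaticity vector
**x** = [a\*, b\*] only — the stain signature is chromatic, and dropping
L\* makes the segmentation robust to illumination level.

Mean shift with a flat kernel of bandwidth **h = 25** (native a/b units)
iterates every feature point to its local mode; modes closer than h/2
are merged, heaviest first. The bandwidth is the method's stated
operating point: it is large enough that a stained scene collapses to
two or three color regions, which is the precondition for a meaningful
two-class Otsu split. Implementation details:

* pixels whose (a, b) fall in the same 0.5-unit bin share one trajectory
  (exact colors collide heavily; the result is unchanged);
* convergence tolerance 0.1 a/b units, at most 100 iterations per
  trajectory.

The mode image (each pixel replaced by its mode's a\* value) is
histogrammed into 256 bins and thresholded by Otsu's criterion
(maximizing between-class variance, computed in closed form and verified
in the tests against an exhaustive search over all cut points). The
foreground is the side with the higher mean a\* — the purple stain is
the red-shifted phase. Holes inside foreground components are filled,
because grain interiors can be pale (pores, exine windows) and the
erosion stage assumes solid regions. Components smaller than
`min_region_area = 150 px` are discarded as debris. Otsu is applied
whole-image, not per region.

## Case I/II decision: the Fibonacci erosion schedule

Each region is eroded with Euclidean disks whose radii follow the
Fibonacci numbers F₁…F₂₁ = 0, 1, 1, 2, 3, …, 6765. Radius 0 is the
identity and supplies the initial object count. Erosion at each radius
is applied to the *original* mask (equivalent to cumulative schedules
for disk elements, with a simpler contract) and is computed as
{distance-to-background > R} from a single Euclidean distance transform,
which is exactly Minkowski erosion by the offset set {‖o‖ ≤ R} (verified
against a brute-force pixel-set oracle). Components smaller than
`min_object_area = 8 px` are ignored when counting (speckle guard).

A convex region (a single grain) stays one object until it vanishes, so
its object count is the same at the start and at the end. A clump of
overlapping ellipses pinches apart at its necks before the fragments
vanish, so the count *near the end* exceeds the count at the start. The
decision rule is exactly this comparison: **Case II iff the final count
(at the last radius with a surviving object) differs from the initial
count**. Radii beyond the frame size can never act on a 278×208 image;
the profile stops early once the mask empties and pads zeros, but the
full 21-term schedule is always generated.

The geometry behind the rule, for two disks of radius r at center
distance d: the union's neck breaks at erosion radius
R = √(r² − (d/2)²), and both fragments survive until R ≈ r, so the split
is observable only if some schedule radius lands in (√(r² − (d/2)²), r).
This window is what constrains both the usable overlap depths and the
grain sizes (see the generator section).

## Seed recovery and GVF snakes

For a Case II region, the eroded fragments at the smallest radius whose
count equals the final count are grown back by simultaneous unit-radius
dilations, clipped to the region, stopping one step before any two
fragments would become 8-connected. The resulting disjoint seeds
initialize one active contour each.

The external force is the gradient vector flow (GVF) of the region's
edge map f = |∇(G_σ ∗ mask)|² (normalized to [0, 1]), relaxed under

u ← u + Δt·[μ∇²u − (u − f_x)(f_x² + f_y²)],

likewise for v, with Δt ≤ 1/(4μ) for stability of the explicit scheme.
Defaults: μ = 0.2, σ = 1.5 px, 80 iterations. The diffusion spreads
boundary forces inward with capture range ≈ √(μ·n_iter) pixels; 80
iterations (~4 px) suffice in the pipeline because the dilated seeds
already hug the region boundary, and the tests that start a snake deep
inside a region use a longer-diffused field.

Each snake starts as the seed's boundary polygon resampled to 64 points
at uniform arc length and follows the standard semi-implicit update
with tension α = 0.1, rigidity β = 0.05, step γ = 1.0 and external
weight κ = 0.6 (canonical values from the active-contour literature; all
config-exposed), resampling every 10 iterations, 100 iterations total.
A contour whose area falls below 10 px² is reported as collapsed; the
pipeline then falls back to the seed boundary itself.

The final contours partition the region: pixels inside exactly one
contour belong to that grain; contested pixels and orphans go to the
contour with the nearest centroid. This guarantees the per-grain masks
are disjoint and their union is exactly the region, and it makes the
separation robust even when two snakes both overrun the neck zone.

## The 33-value descriptor

Each separated grain, mapped onto the Lab image, yields:

* **Shape (6)** — bounding-box length MA and width mA (axis-aligned),
  area A (pixel count), perimeter P, roundness R = 4πA/P², compactness
  C = A/P². P is the length of the polygon through the ordered border
  pixel centers (Moore-neighbor trace): a 10×10 square has P = 36.
  Because the chain length overestimates a smooth perimeter by up to
  8.2% (a digitized line at angle θ has length ratio
  cos θ + (√2−1)·sin θ), a rasterized circle measures R ≈ 0.90 rather
  than 1; R is still monotone in elongation, which is what matters for
  discrimination. C = R/(4π) identically — both are kept because the
  descriptor schema fixes 6 shape slots.
* **First-order texture (5 × 3 channels = 15)** — mean, sample median,
  population variance (divisor N), standard deviation, and histogram
  entropy in bits over 256 bins spanning the channel's native range
  (L ∈ [0, 100]; a, b ∈ [−128, 127]).
* **Second-order texture (4 × 3 channels = 12)** — contrast,
  correlation, energy and local homogeneity of a gray-level
  co-occurrence matrix per channel: 32 equal-width levels over the
  native range, distance 1, the four offsets 0°/45°/90°/135° with both
  pixels inside the mask, symmetrized, offset-averaged and normalized.
  Homogeneity uses 1/(1+|i−j|); correlation is defined as 0 when a
  marginal deviation vanishes.

The flattened order (documented in `FEATURE_NAMES`) is: 6 shape, then
the five first-order statistics for L, a, b, then the four
co-occurrence statistics for L, a, b — 33 values, all translation
invariant.

## Classification and quality indicators

Three learner families are evaluated under stratified s-fold cross
validation (s = 2, 5, 10; stratification matters because the smallest
classes have few tens of members):

* **MLP** — one hidden layer of ⌈(33+12)/2⌉ = 23 units, SGD with
  learning rate 0.3 and momentum 0.2, up to 500 epochs, standardized
  inputs;
* **RTF** — 100 unpruned random trees, √33 features per split, majority
  vote;
* **BN** — naive Bayes with Gaussian class-conditional densities (the
  features are continuous, so count smoothing does not apply).

All indicators derive from the pooled actual×predicted confusion
matrix. Per class: TPR = TP/(TP+FN), PPV = TP/(TP+FP),
FPR = FP/(FP+TN), F1 = 2·PPV·TPR/(PPV+TPR) (0 when both rates are 0).
Summary rows are support-weighted, so the weighted TPR equals
trace/total identically. The metrics engine is validated against the
published confusion matrices of a 618-grain, 12-species benchmark
(stored as a text fixture), reproducing the published weighted
recall/precision values to three decimals.

Feature tables are read and written as CSV and as Weka-dialect ARFF
(numeric attributes, nominal class last, missing values rejected).

## The synthetic-scene generator

The generator is the package's source of ground-truthed test data; its
defaults define the study conditions for the acceptance suite.

* **Scale** — 1 px ≈ 0.5 µm, so the 10–60 µm grain range maps to
  20–120 px diameters; the 12 class means span 26–84 px so that several
  grains fit a 278×208 frame.
* **Classes** — each species has a fixed prior over equivalent
  diameter (±3%), elongation a/b (1.05–1.40), Lab stain shade around
  (L 45, a 35, b −25), exine-ring width (0–3.5 px, rendered as a
  darker, redder rim band) and per-channel texture noise σ
  (0.6–2.4 Lab units). The per-class separation is deliberate: the
  acceptance surface is pipeline correctness, not classifier
  difficulty.
* **Clumps** — overlapping grains come in conspecific pairs/triples
  (clumped grains on real slides typically originate from one anther,
  so clump members share a species and hence a size class). Members are
  chained at center separation c·(r₁(φ)+r₂(φ)), c ∈ [0.84, 0.96], where
  r(φ) is each ellipse's radius along the center line: rigid grains in
  a monolayer interpenetrate only a small fraction of their directional
  radii, and this keeps the neck shallow relative to the grains.
  Because r(φ) ≥ b, every clump also respects the
  d ≥ 0.8·(b₁+b₂) separability floor that the erosion-split geometry
  requires.
* **Size placement relative to the schedule** — a clump is detected
  only if a Fibonacci radius falls between the neck-break radius and
  the fragments' vanishing radius, and a fragment only counts while its
  residual area clears the 8 px speckle guard. Class sizes are
  therefore chosen so that the residual ellipse area
  π(a−F)(b−F) at every sub-critical Fibonacci radius F stays decisively
  above (or the size below) the guard across the whole ±10% sampling
  band — otherwise clump members near a schedule radius would be
  counted inconsistently. This mirrors the fact that the erosion rule
  works on real data where grain sizes and overlap depths are benign;
  it is a property of the emulated conditions, not of the algorithm.
* **Background and clutter** — pale background (L 92, a 2, b 2) with
  faint sensor noise, plus 2–5 low-saturation elliptical smears
  ("Vaseline", L 85, a 4, b 12) kept clear of grains. The grain/
  background chroma distance under the default stain (~43 a/b units)
  exceeds the mean-shift bandwidth but not 2h; the ≥99%
  foreground-coverage property is therefore tested at its stated
  condition (≥ 2h separation, zero noise) with an explicitly
  constructed scene.
* **Rendering** — scenes are composed in Lab and converted to 8-bit
  sRGB; ellipse edges get an anti-aliasing ramp centered on the true
  boundary so the rendered footprint matches the ground-truth mask to
  within half a pixel. Ground-truth masks are the exact rasterized
  ellipse interiors, independent of noise. Everything is deterministic
  given the scene seed.

**What the generator does not emulate** — real pollen morphology
(pores, colpi, sculptured exine), optics (defocus, vignetting, chromatic
aberration), stain variability within a grain beyond white noise,
debris touching grains, grains cut by the frame, and clumps of more
than three or of mixed species. Passing the synthetic suite therefore
demonstrates the pipeline's geometric and statistical correctness under
the stated conditions, not field-ready accuracy on arbitrary slides.

## Degenerate inputs and tie-breaks

* Otsu ties resolve to the lowest cut index; a single-mode scene is an
  error ("nothing to threshold").
* An empty region or empty value list is an error everywhere; a
  single-pixel grain gets P = 1 to keep ratios finite.
* `extract_seeds` on a Case I profile is an error; a snake that
  collapses raises, and the pipeline substitutes the seed boundary.
* Erosion profiles record zeros after the mask empties; the final count
  is read from the last radius with a survivor.
* Cross-validation warns and degrades to best-effort stratification
  when a class has fewer members than folds.

## Problem sizes

The default test suite and the acceptance script run 50 scenes of
278×208 px with 1–4 grains each (overlap probability 0.5) — about half
a minute end to end — plus a 144-grain feature dataset (12 per class)
for the classifier checks. These sizes were chosen as the smallest at
which every stage (multi-grain scenes, triples, all 12 classes) is
exercised with stable statistics.
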