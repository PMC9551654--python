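# Methods

This note records the models implemented in `lodgepoint`, the defaults and
why they were chosen, and the places where the design was genuinely open.

## Lodging severity model

A lodged stem of sloping length h₁ whose canopy sits at height h₂ makes an
angle θ with the vertical satisfying sin(90° − θ) = h₂/h₁, so

    θ  = 90° − arcsin(h₂ / h₁)        θ ∈ [0°, 90°]
    LA = 2θ/π = θ/90°                 angle severity in [0, 1]
    LI = LA · LR                      lodging index in [0, 1]

with LR the fraction of plot area lodged. The three anchor cases pin the
convention: h₂ = h₁ → θ = 0 (upright, LA = 0); h₂ = 0 → θ = 90° (flat,
LA = 1); h₂ = h₁/2 → θ = 60°, LA = 2/3. Field protocols measure 3–5
(h₁, h₂) samples per plot; `measure_plot` averages θ across samples before
computing LA.

**Double-threshold degrees.** Plots are binned by the mean μ and standard
deviation α of LI over the surveyed population: non-lodging [0, μ−α),
slight [μ−α, μ), moderate [μ, μ+α), severe [μ+α, 1]. The reference survey
of 360 plots gives μ = 0.40, α = 0.274, hence cuts 0.126 / 0.40 / 0.674.
Open choices resolved here: interval edges are half-open on the right
(a boundary value belongs to the upper, more severe class) so the four
intervals partition [0, 1] deterministically; α is the population
(divide-by-n) standard deviation, matching the divide-by-n covariance used
in the alignment transform.

## Ground separation and normalization

ExG is computed on chromatic coordinates, ExG = 2g − r − b with
r = R/(R+G+B) etc., because the working threshold 0.0729 is only plausible
on that normalized scale (the raw 2G−R−B form spans ±510). Black points
(R+G+B = 0) score 0. Ground is ExG *below* the threshold — green canopy
scores high (+2 for pure green), soil near 0. ExG is applied per point;
the colour carried by each photogrammetric point is the orthomosaic pixel
it was reconstructed from.

The DEM is IDW-interpolated from ground points on a coarse grid (default
0.1 m — fine enough to track gentle terrain undulation, coarse enough to
average over canopy gaps) and sampled bilinearly during subtraction.
Negative normalized heights are kept, not clamped: they are a visible
diagnostic of interpolation bias, and rendering clips anyway.

## Principal-axes (Hotelling) alignment

The transform P′ = V(P − m) uses the centroid m and the eigenvectors V of
the population covariance, rows sorted by descending eigenvalue, computed
in the centered form for numerical stability (algebraically identical to
(1/n)ΣPPᵀ − mmᵀ). Eigenvector signs are not determined by the
decomposition, so a fixed convention makes output deterministic: the
smallest-variance axis (height, for a field plot) is flipped toward world
up; the largest-variance axis toward world +x (falling back to +y when
orthogonal to x); the middle axis is their cross product, forcing
det(V) = +1 — a proper rotation, never a mirrored field. Near-equal
eigenvalues keep the decomposition's order and are logged.

**Pipeline composition.** In `process_plot` the alignment frame is
estimated from the normalized *ground* points and applied rigidly to the
canopy. The plot frame is physically the ground plane; including the
canopy in the covariance lets lodged patches (height dips correlated with
position) tilt the recovered height axis by several degrees, which injects
a spurious height gradient of ±0.1–0.3 m across a 7.8 m plot. With the
ground-plane frame, lodged-patch heights are recovered to better than
0.01 m on synthetic plots. The raster is likewise built from vegetation
points only (a canopy height model): interpolating visible-soil points
into the surface drags patch heights toward zero in proportion to the
soil fraction. The rasterization step adds back the height component of
the dropped centroid translation (V₃·m) so raster values remain height
above ground.

## Grid division and IDW

rows = round(Δx/d), cols = round(Δy/d), rounding half away from zero so
the reference 7.8 m / 0.01 m gives exactly 780 despite binary floating
point. Cell centres sit at origin + (i + 0.5)d.

IDW uses inverse-square weights normalized to sum to 1 (so estimates are
convex combinations bounded by the neighbor extremes). The literal
formula sums over all m samples; at ~10⁵ points per plot that is
O(cells·points), so the default restricts to the k = 12 nearest samples
via a k-d tree, and `k_neighbors = 0` switches to the exact all-samples
form (used by the tests as an equivalence oracle). The weight is singular
at distance 0; cell centres within 1e-9 m of a sample take the mean of
the coincident samples.

Interpolation quality is scored by holding out a seeded random 20% of
samples and predicting them from the rest: MAE = mean|wᵢ|,
SD = √(mean wᵢ²), and the median of |wᵢ| (the published benchmark values
are all positive, so the median is read on the absolute residuals), all
reported in millimetres. The reference benchmark errors for two
alternative interpolators (local linear embedding, biharmonic spline) are
bundled as constants; only IDW is implemented, the others are explicit
registry stubs, and `interpolation_benchmark_report` derives the
percentage error reductions — e.g. 49.6% MAE reduction vs local linear
embedding at the filling stage — from the stored values at run time.
(The bundled maturity-stage *percentages* quoted alongside the benchmark
table in its original report are not consistent with the table's own
values; this package only reproduces the filling-stage arithmetic, which
is self-consistent.)

## CNN classifiers

AlexNet, VGG16 (13 conv + 3 FC layers) and MobileNetV2 (inverted
residuals with linear bottlenecks) are implemented on a small NumPy
framework written for this package (im2col convolution, a vectorised
depthwise path, batch normalization, ReLU/ReLU6, max/adaptive-average
pooling, dropout, Adam, softmax cross-entropy; gradients verified against
finite differences). Layer plans are the canonical published
architectures, so the trainable-parameter totals at a 1000-class head are
exactly 61,100,840 / 138,357,544 / 3,504,872. Training defaults follow
the field study: Adam at 0.001, batch 4, ≤400 epochs, early stop after 30
epochs without *strict* validation-accuracy improvement (ties keep the
earlier epoch), best-validation weights restored. Everything is seeded:
initialisation, shuffling, dropout, augmentation.

Open choices resolved here: multi-class precision/recall/F1 are
macro-averaged (classes absent from a test set are excluded and logged);
models train from random initialisation (no pretrained weights are
bundled); input images are resized bilinearly to the network input and
standardised to zero mean, unit half-range.

**Dataset protocol.** Augmentation (seeded rot90/rot270/horizontal/
vertical flips) runs offline *before* the split, reproducing the
360 → 1,000 → 640/160/200 counts of the reference protocol at 16:4:5;
because augmented copies of one plot can then appear on both sides of a
split boundary, `split_by_plot` is provided as the leakage-free
alternative and is the recommendation for real studies. The stratified
split allots each class by largest-remainder rounding and then repairs
single samples between parts until the global sizes equal the
largest-remainder targets, keeping every class within one sample of the
16:4:5 proportions.

## Synthetic wheat field

The generator emulates the surveyed conditions: 7.8 m × 3.8 m plots,
uniform xy sampling at 500 points/m² (photogrammetric densities are of
this order; tests use 300/m² to keep runtimes short), gently sloping
terrain (1–2 cm/m) with an 8 cm sinusoidal undulation of 6 m wavelength,
canopy at h₁ = 1.0 m, Gaussian height noise σ = 0.02 m, and ~20% of
points hitting bare soil so the ExG/DEM stages have real work. A
contiguous axis-aligned rectangular patch of exact area fraction LR is
lodged at canopy height h₁·cos θ — the geometric inverse of the severity
model, so the lodging formulas are exactly recoverable. Soil
(150, 100, 60) and canopy (60, 140, 60) colours receive a
chromaticity-neutral brightness factor (0.8–1.2) plus ±5 per-channel
jitter, keeping soil ExG below ~0.04 and canopy above ~0.5: the 0.0729
threshold recovers the generator's soil partition exactly.

Per-class lodging angles are drawn from disjoint ranges — 0–10°
(non-lodging), 25–40° (slight), 45–60° (moderate), 70–90° (severe) —
whose implied canopy heights fall into the four observed bands
(>0.9 m, 0.7–0.9 m, 0.5–0.7 m, <0.5 m); LR is then solved so LI lands in
the requested class interval under the reference thresholds.

What the generator does **not** emulate: per-plant canopy structure and
occlusion, photogrammetric reconstruction artefacts (holes, ghost
points), mixed pixels at soil/canopy boundaries, intermediate lodging
angles within one patch, or irregular patch shapes (a circular option
exists). Passing the synthetic suite therefore demonstrates the
correctness of the geometry, interpolation and learning machinery under
the stated field conditions, not classification accuracy on real wheat
imagery.

## Scaled-down end-to-end experiment

The synthetic classification experiment runs 160 plots at 300 points/m²,
rasters at d = 0.06 m, augmentation to 500 images, and a MobileNetV2 at
width multiplier 0.5 and 48 × 48 input, batch 16, ≤30 epochs — problem
sizes chosen so the whole experiment completes in a few minutes on one
CPU while leaving the learning task non-trivial. Batch 16 (rather than
the full-scale default 4) is used at reduced resolution because the final
feature maps shrink to 1–2 px and batch-norm statistics over 4 images
become too noisy to train reliably; at the full 224 × 224 resolution the
7 × 7 maps give batch 4 ample statistics. The trained model reaches
≥0.90 test accuracy on the four lodging degrees (0.96 at the default
seed).

## Numerical notes and limitations

- IDW exact-hit tolerance 1e-9 m; orthonormality and diagonalization
  tolerances 1e-9; eigenvalue degeneracy flagged below 1e-12 relative.
- `make_grid` requires positive extents; degenerate (single-cell) grids
  are allowed.
- DEM sampling raises on points outside its extent; the default DEM grid
  pads the ground bounding box by one cell so vegetation at the plot edge
  stays inside.
- Rank-deficient clouds (coplanar/collinear) are transformed with a
  logged note; fully degenerate clouds (all points identical) are
  rejected.
- The NumPy CNNs are CPU-bound: full-size 224 × 224 training is supported
  but slow; the width/input scaling knobs exist precisely so experiments
  match available compute.
- LAS/LAZ input, georeferenced CRS handling, and automatic LR estimation
  from imagery are out of scope.
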