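# lodgepoint

Assessment of crop lodging (wind/rain-flattened stems) from UAV-derived
field point clouds. Photogrammetric point clouds of wheat plots are
cluttered, unordered 3D data; `lodgepoint` reduces them to regular 2D
canopy-height images and classifies each plot into one of four lodging
degrees with a CNN.

The pipeline:

1. **Ingest / crop** — plain-text XYZ(+RGB) clouds, cut into rectangular
   plots (default 7.8 m x 3.8 m).
2. **Normalize** — the Excess Green index ExG = 2g − r − b (chromatic
   coordinates) separates soil from canopy at a threshold of 0.0729; a DEM
   interpolated from the ground points is subtracted so z becomes height
   above ground.
3. **Align** — the Hotelling (principal-axes) transform
   P′ = V(P − m), with m the centroid and V the eigenvectors of the
   population covariance C = (1/n) Σ (Pₖ−m)(Pₖ−m)ᵀ sorted by descending
   eigenvalue, rotates the plot into its own frame.
4. **Rasterize** — a grid with spacing d (rows = Δx/d, cols = Δy/d; the
   reference plot at d = 0.01 m gives 780 × 380 cells) is filled by
   inverse-distance-weighted interpolation
   Z = Σ Kᵢ Zᵢ, Kᵢ = dᵢ⁻² / Σ dⱼ⁻², and colour-rendered to an image.
5. **Label** — the lodging index LI = LA · LR, with LA = 2θ/π the angle
   severity (θ = 90° − arcsin(h₂/h₁)) and LR the lodged-area fraction, is
   binned by the double-threshold rule: cut points μ−α, μ, μ+α from the
   mean and standard deviation of LI over plots (the reference survey gives
   0.126 / 0.40 / 0.674).
6. **Classify** — AlexNet, VGG16 or MobileNetV2 (implemented on the
   package's own NumPy CNN framework) trained with Adam, learning rate
   0.001, batch size 4, ≤400 epochs, early stopping after 30 stale epochs;
   evaluated by per-class TP/FP/TN/FN, accuracy, precision, recall and F1.

A synthetic wheat-field generator with exact ground truth (terrain, canopy
height h₁, lodged patches at angle θ with canopy h₂ = h₁·cos θ, soil/canopy
colours, Gaussian noise) makes every stage testable without field data.

## Worked example

Simulate one moderately lodged plot (θ = 53°, LR = 0.5), run the pipeline,
and read the lodging parameters back off the raster:

```python
import numpy as np
from lodgepoint import FieldSimConfig, generate_plot, process_plot, classify_LI
from lodgepoint.pipeline import raster_patch_mean

cfg = FieldSimConfig(point_density=500, seed=11)
cloud, truth = generate_plot(cfg, theta=53.0, LR=0.5, rng=np.random.default_rng(11))
raster, hot = process_plot(cloud, raster_spacing=0.05)

h2 = raster_patch_mean(raster, hot, truth.patch_bounds)   # lodged canopy height
h1 = float(np.percentile(raster.values, 90))              # upright canopy height
theta = np.degrees(np.arccos(min(h2 / h1, 1.0)))
LA = theta / 90.0
LR = float((raster.values < (h1 + h2) / 2).mean())
LI = LA * LR
```

Output:

```
raster: 156 x 77 cells at d = 0.05 m
canopy height (upright): 1.010 m   lodged patch: 0.606 m
lodging angle theta: 53.1 deg  (injected 53.0)
LA = 0.590   LR = 0.497  (injected 0.500)
LI = 0.293   degree: slight  (truth: slight)
```

The raster recovers the injected lodging angle to 0.1° and the lodged-area
fraction to 0.003; the plot is labelled *slight* lodging, in agreement with
the generator's truth record.

The same flow is available from the shell:

```sh
lodgepoint simulate --plots 8 --seed 1 --out sim/
lodgepoint normalize --in sim/field.txt --out norm.txt
lodgepoint align --in norm.txt --out aligned.txt --report transform.json
lodgepoint rasterize --in aligned.txt --spacing 0.05 --out plot.png
lodgepoint run --config pipeline.yaml        # end-to-end with training
```

## Layout

```
src/lodgepoint/
  pointcloud.py   XYZ-text / PLY I/O, plot layout, cropping
  normalize.py    ExG ground separation, DEM, height normalization
  hotelling.py    principal-axes transform
  raster.py       grid division, IDW, rendering, interpolation metrics
  lodging.py      lodging angle / LA / LR / LI, double-threshold classes
  nn.py           NumPy CNN framework (conv, BN, pooling, Adam, ...)
  models.py       AlexNet / VGG16 / MobileNetV2 builders
  classify.py     augmentation, 16:4:5 split, training, evaluation
  synthetic.py    wheat-field simulator with ground truth
  pipeline.py     end-to-end runner
  cli.py          `lodgepoint` command-line interface
```

See `docs/methods.md` for the modelling choices and their rationale.
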