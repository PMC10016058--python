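# tonomap

Functional parcellation of the mouse auditory cortex from transcranial
intrinsic-signal imaging, stereotaxic registration of the resulting area
maps, and quantitative comparison against a brain-atlas parcellation.

Mouse auditory cortex contains at least four tonotopically organised
fields — A1, the ventral (VAF) and anterior (AAF) auditory fields, and
the secondary cortex A2 — plus tone low-responsive margins (the
dorsoposterior field DP and the centre region CTR). Their locations
relative to the skull landmarks bregma and lambda vary across animals by
hundreds of micrometres, so targeting them by standardized atlas
coordinates (Au1/AuD/AuV) is error-prone. This package implements the
full analysis chain needed to measure that variability, and ships a
synthetic-data generator with known ground truth so the whole chain is
testable end to end:

* **`tonomap.synthetic`** — populations of synthetic mice: Gaussian
  frequency-domain layouts with the field's gradient conventions,
  rendered widefield trial stacks (hemodynamic blur, acquisition noise),
  and inked skull reference marks with human alignment error.
* **`tonomap.imaging`** — trial stacks to response maps: per-trial
  fractional change (response / baseline − 1), trial averaging, Gaussian
  filtering (σ = 2 px), and Richardson–Lucy deconvolution against a 2-D
  Gaussian PSF (σ = 200 µm).
* **`tonomap.segmentation`** — semiautomated parcellation: seed-ROI
  centroids (mean of the peak pixel and the amplitude-weighted centre of
  mass), 60 %-of-peak domain masks, amplitude-weighted dividing lines for
  overlapping domains, morphological smoothing (30/150 px disk opening /
  closing at the reference pixel scale), inter-area overlap removal, and
  the DP/CTR constructions at a 20 % threshold.
* **`tonomap.registration`** — the pixel → stereotaxic transform from
  three skull marks at (P, V) = (−2.5, 1.5), (−3.5, 1.5), (−3.5, 2.0) mm
  scaled by BLdist/4.2, with the three coordinate systems
  (bregma-absolute, lambda-absolute, B–L-normalized) and the
  histology-based coordinate estimation used for dye deposits.
* **`tonomap.atlas`** — a topographical (AP, DV) surface map of
  Au1/AuD/AuV built from a per-section border table, including the
  split-equal patch for the single-section AuV discontinuity. The
  shipped table is a clearly-labelled synthetic stand-in with the same
  schema as a user-measured one.
* **`tonomap.metrics`** — population statistics: overlap fractions,
  classification accuracy (e.g. A1 → Au1) and targeting accuracy
  (e.g. Au1 → A1), cross-animal mask overlap over ordered mouse pairs,
  pairwise centroid distances, the inter-experimenter marking-error
  metric, probability contour maps, map-geometry metrics (extents,
  angles α/β, the A1–AAF gap), N-way ANOVA variance decomposition, and
  Bonferroni-corrected rank-sum comparisons.

`tonomap.pipeline` ties the stages together and `tonomap` is also a CLI
(`tonomap simulate / segment / atlas build / quantify / report`).

## Worked example

Generate six synthetic mice, run imaging → segmentation → registration,
and compare the registered maps with the synthetic atlas:

```python
import numpy as np
from tonomap import atlas, metrics, pipeline

run = pipeline.run_synthetic_population(n_mice=6, seed=0)
print(f"domains detected: {100 * run.detection_rate:.1f}% "
      f"(median centroid error {np.median(run.centroid_errors_um):.0f} um)")

table = atlas.patch_discontinuity(atlas.synthetic_atlas_table())
rasters = atlas.atlas_rasters(atlas.build_surface_map(table),
                              run.population.grid)
a1_to_au1 = [metrics.classification_accuracy(m, rasters)["A1->Au1"]
             for m in run.population.mice]
print(f"A1 -> Au1 classification accuracy: {100 * np.mean(a1_to_au1):.0f}%")

dists = metrics.centroid_pairwise_distances(run.population)
print(f"inter-animal centroid distance: "
      f"{1000 * dists['mean_ap_mm']:.0f} um AP, "
      f"{1000 * dists['mean_dv_mm']:.0f} um DV "
      f"({dists['n_pairs']} centroid pairs)")
```

prints

```
domains detected: 100.0% (median centroid error 21 um)
A1 -> Au1 classification accuracy: 94%
inter-animal centroid distance: 319 um AP, 242 um DV (60 centroid pairs)
```

All 72 rendered frequency domains were found, with centroids recovered to
~21 µm; with this seed’s six animals, 94 % of A1’s extent falls inside
the synthetic atlas’s Au1; and corresponding frequency-domain centroids
sit a few hundred micrometres apart across animals — the inter-animal
variability the analysis exists to quantify.

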