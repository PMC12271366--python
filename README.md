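# nlomics

Quantitative analysis of myocardial scar tissue in two-channel non-linear
optical microscopy.  Second harmonic generation (SHG) images fibrillar
collagen label-free; two-photon excited fluorescence (TPEF) images the
cardiomyocytes.  After a myocardial infarction, healing replaces muscle
with collagen-rich scar, and the amount, morphology and orientation of that
collagen — together with texture descriptors of both channels — separate
healthy myocardium from the border zone and mature fibrosis.  `nlomics` is
for researchers who want that analysis as a tested, reproducible pipeline
rather than a collection of ImageJ/Matlab steps.

The package provides:

* **a synthetic fibrous-tissue generator** with ground truth, emulating the
  three tissue phenotypes (muscle / border / fibrosis) as parameterized
  fiber ensembles, so every downstream stage is testable without access to
  animal data;
* **preprocessing** — multi-scale Frangi vesselness for collagen
  enhancement, maximum Rényi (Kapur) entropy and Li minimum-cross-entropy
  thresholds computed on pooled stack histograms, foreground masks, block
  binning and background renormalization;
* **16 conventional features** per frame: the collagen intensity ratio
  C_I = mean(SHG)/(mean(SHG)+mean(TPEF)) and segmentation ratio
  C_S = N_SHG/(N_SHG+N_TPEF); fiber count and mean/sd of traced fiber
  length, width and straightness; and circular statistics — mean vector
  length MVL = √(X̄²+Ȳ²) with X̄ = Σ f(θ)cos θ, Ȳ = Σ f(θ)sin θ over the
  normalized 1°-binned orientation histogram f(θ), the range R (smallest
  circular arc holding more than half the histogram's weight), and the
  axial SHG–TPEF mean-angle mismatch;
* **an IBSI-style 2-D radiomics panel** per modality (intensity, histogram,
  intensity-volume histogram, morphology, GLCM, GLRLM, GLSZM, NGTDM,
  NGLDM), every feature verified against brute-force references;
* **KDE-overlap harmonization** — features whose train/test kernel-density
  overlap falls below 0.75 are discarded as batch-affected — plus
  Kruskal–Wallis and Wilcoxon rank-sum significance tests and the
  radiomics-vs-conventional Pearson correlation matrix;
* **Monte-Carlo stacked-ensemble classification** with class-balanced
  validate splits, fold-internal preprocessing, synthetic minority
  oversampling, permutation-importance feature weights, and confusion
  matrices for the 3-class and the collapsed healthy-vs-pathological task.

## Worked example

Generate one synthetic fibrosis frame, segment both channels, trace the
collagen fibers and compute the conventional feature vector:

```python
import numpy as np
from nlomics import (default_presets, generate_image,
                     segment_collagen_pipeline, segment_tpef_pipeline,
                     trace_fibers, conventional_feature_vector)

presets = default_presets()
(shg, tpef), truth = generate_image(presets["fibrosis"], size_px=512, seed=42)
shg_bin = segment_collagen_pipeline(shg[None])[0]
tpef_bin = segment_tpef_pipeline(tpef[None])[0]
fibers = trace_fibers(shg_bin, pixel_size_um=508 / 512)
features = conventional_feature_vector(shg, tpef, shg_bin, tpef_bin, fibers)
for name in ("collagen_intensity", "collagen_segmentation", "fiber_count",
             "fiber_length_mean", "fiber_width_mean", "shg_mvl", "shg_range"):
    print(f"{name:24s} {features[name]:.3f}")
```

prints

```
collagen_intensity       0.229
collagen_segmentation    0.298
fiber_count              48.000
fiber_length_mean        45.440
fiber_width_mean         5.220
shg_mvl                  0.707
shg_range                1.030
```

— a collagen-dominated frame: 23% of the total intensity and 30% of the
segmented pixels are collagen, 48 fibers of ~45 µm mean length and ~5 µm
mean width were traced, and the SHG orientation histogram is moderately
disordered (MVL 0.71, range ≈ 1.0 rad).  A muscle frame from the same
generator gives C_I ≈ 0.09 and C_S ≈ 0.04 with a handful of short thin
fibers.

The full pipeline — simulate, extract features, screen, test significance,
train and evaluate — runs from the shell:

```bash
nlomics all --seed 1 --out runs/demo          # every stage, all artifacts
nlomics simulate --seed 1 --out runs/images   # just the labeled TIFF stacks
nlomics screen --features runs/demo/features.csv --threshold 0.75 --out runs/scr
```

`runs/demo/report.json` then holds the cross-validation accuracy (mean ± sd
over Monte-Carlo folds), the held-out-subject 3-class and binary confusion
matrices, and the per-feature ranking weights.

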