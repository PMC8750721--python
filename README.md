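# calyxscan

Pixel-level detection of codling-moth (*Cydia pomonella*) infestation in
apples from shortwave-NIR hyperspectral images (900–1700 nm).

Codling-moth larvae bore into apples — usually at the calyx (blossom) end —
leaving externally invisible damage that changes the tissue's NIR
absorption (water and C–H overtone bands near 950, 1200 and 1400 nm).
`calyxscan` implements the full screening workflow for people working on
optical fruit sorting and postharvest pest detection:

1. **ENVI IO** — read/write header + raw hypercube pairs (bil/bip/bsq,
   uint16/float32), wavelength-addressed band lookup.
2. **Reflectance calibration** — `R = (R0 − Rd)/(Rw − Rd)` against
   white/dark references, full-frame or push-broom line-averaged.
3. **Automatic calyx ROI** — Otsu thresholding at 1084 nm, hole-filling to
   find the dark cavity inside the fruit disk, disk erosion, centroid of
   the largest component, 50 px circular ROI; pixel spectra extracted and
   labelled. Whole-fruit mean-spectrum and manual 10×10 rectangle modes
   are included for comparison.
4. **Preprocessing** — wavelength trimming, maximum normalization,
   Savitzky–Golay smoothing (order 2, window 31), train-mean centering.
5. **Kennard–Stone 70/30 split**, deterministic max–min sample selection.
6. **PCA + classifier bank** — LDA, kNN, SVM, random forest, gradient tree
   boosting, PLS-DA, AdaBoost; per-class precision/recall/F1
   (F1 = 2RP/(R+P), "infested" positive) and stratified 5-fold CV.
7. **Sequential forward wavelength selection** — greedy CV-wrapper
   selection producing an ordered band list and accuracy-vs-k curve, the
   basis for cheap multispectral deployments.
8. **Synthetic scene generator** — apple hypercubes with ground truth
   (endmember spectra, masks, references, noise model), so the whole
   pipeline is testable end-to-end without proprietary fruit data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from calyxscan import (SceneConfig, generate_scene, calibrate, acquire_roi,
                       extract_pixel_spectra)

raw, refs, truth = generate_scene(SceneConfig(seed=3))
cube = calibrate(raw, refs)                     # counts -> reflectance
roi = acquire_roi(cube)                         # automatic calyx circle
print("centroid:", roi.centroid, "true:", truth.calyx_center)
print("ROI pixels:", roi.n_pixels)

table = extract_pixel_spectra(cube, roi.mask, raw.meta["label"])
print("table:", table.spectra.shape)
```

prints

```
centroid: (89.5, 107.5) true: (89.5, 107.5)
ROI pixels: 1976
table: (1976, 128)
```

— the segmentation found the calyx centre exactly, the 50 px circle holds
1976 lattice pixels, and each pixel carries a 128-band spectrum labelled
with its apple's class.

A full study (simulate → calibrate → ROI → preprocess → split → PCA →
classify → select) runs from one config:

```bash
calyxscan run --config study.yaml --seed 7
calyxscan simulate --preset strong --n-control 2 --n-infested 4 --seed 42 --out scenes/
calyxscan roi --in scenes/infested_00_raw.hdr --seg-nm 1084 --diameter 50 --out roi.png
```

Run outputs land in the configured directory: `reports/*.json` (per
classifier × partition, per-class metrics), `tables/*.csv` (flat metrics,
CV summary, selection curve), `resolved_config.yaml` and `run.log`.

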