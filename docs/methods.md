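# Methods

`calyxscan` implements a pixel-level workflow for screening apples for
codling-moth (*Cydia pomonella*) infestation in shortwave-NIR hyperspectral
images (nominally 900–1700 nm). Larvae typically enter the fruit at the
calyx (blossom) end, so the discriminative tissue sits in a small
neighbourhood of the calyx cavity; the workflow therefore centres its region
of interest there automatically rather than averaging over the whole fruit.
This note records the models, the defaults and why they were chosen, what
the synthetic data does and does not emulate, and the numerical conventions.

## Reflectance calibration

Raw push-broom counts are converted to relative reflectance with the
standard two-point correction

    R = (R0 − Rd) / (Rw − Rd)

where `R0` is the sample cube, `Rd` the dark-current image and `Rw` the
white-panel image. References may be full frames or per-(column, band) line
averages (`collapse_reference`); the line-average form is the push-broom
convention and is what the synthetic generator emits. Denominator entries
smaller than `epsilon` (default 1e−6 on the native count scale) produce 0
and are counted in the output metadata. Negative reflectance (sample darker
than the dark reference, possible under noise) is preserved by default and
only clipped on request, matching chemometrics practice of not destroying
information before preprocessing.

## Automatic calyx ROI

The acquisition chain at the segmentation band (default 1084 nm, where
flesh/calyx contrast is strong):

1. **Threshold** — Otsu's between-class-variance criterion on the 256-bin
   band histogram separates bright fruit flesh from everything dark. The
   dark calyx cavity falls on the *background* side of this threshold, which
   is why a second rule is needed.
2. **Cavity isolation** — filling the holes of the flesh mask yields the
   fruit disk; the sub-threshold pixels inside the disk are the calyx
   candidate. A contrast guard (candidate must be at least 20% darker than
   flesh on average) rejects scenes with no real cavity, where a threshold
   would otherwise "find" noise.
3. **Erosion** — binary erosion with a disk structuring element (default
   radius 2; out-of-bounds counts as background) removes thin dark fringes
   and leaves a solid blob.
4. **Centroid** — arithmetic mean of the largest 8-connected surviving
   component's coordinates.
5. **Circular ROI** — pixels whose centres lie within `diameter/2`
   (inclusive) of the centroid, default diameter 50 px, clipped at borders.

Two comparison extraction modes exist: the whole-fruit mean spectrum (one
observation per apple) and a manual-style 10×10 rectangle at the calyx
centroid (100 pixels per apple).

Every ROI pixel inherits its apple's label. This transfers apple-level
ground truth to pixels and is a known label-noise source: calyx-cavity
pixels inside the circle look the same in both classes, which caps
attainable pixel accuracy below 1 in proportion to the cavity's share of
the ROI.

## Spectral preprocessing

Fixed order, applied to pixel-spectra tables: wavelength trimming (default
950–1650 nm, removing noisy detector edges) → maximum normalization (each
spectrum divided by its own maximum, removing path-length/scatter gain) →
Savitzky–Golay smoothing (second-order polynomial, window 31 bands,
polynomial-fit edge handling so no bands are lost) → mean centering. The
centering mean is fitted on the training partition and reapplied to
validation data; fitting it globally would leak validation information into
the features.

## Kennard–Stone splitting

The 70/30 train/validation split uses classical Kennard–Stone max–min
selection on Euclidean distances in full band space: seed with the most
distant pair, then repeatedly add the point farthest from the selected set.
Deterministic; ties break toward the lower row index. Distances are
computed on the spectra *before* mean centering — subtracting one constant
vector from every row changes no pairwise distance, so the split is
identical to one computed after centering while the centering statistics can
still be fitted on the training rows only. The split pools pixels across
apples (matching the pixel-level design); note that pixels of one apple can
then appear on both sides, which is fine for the synthetic studies here
because apples differ only by a scalar gain that normalization removes, but
would be optimistic on real data with apple-specific spectral signatures.

## Classification

PCA (covariance eigenstructure computed by SVD of the centred training
matrix; component signs fixed so the largest-magnitude loading entry is
positive) reduces the preprocessed spectra to 3 components by default — on
data of this shape the first three carry ~95–98% of the variance — with a
cumulative-variance-target mode available. The classifier bank: LDA, kNN
(k=5), RBF-SVM (C=1), random forest (500 trees), gradient tree boosting
(500 trees, depth 3, learning rate 0.1), PLS-DA (PLS regression on a
{0,1}-coded response, 10 latent variables, 0.5 threshold) and AdaBoost (100
stumps). None of these settings are tuned to any particular dataset; all
are config-exposed and recorded in reports. "Infested" is the positive
class; reports carry per-class precision, recall, F1 = 2RP/(R+P) and total
accuracy, plus stratified 5-fold CV mean ± sd.

## Wavelength selection

Greedy sequential forward selection: at each step every unselected band is
appended to the current set and scored by stratified-CV accuracy (F1
optional) with a fixed criterion classifier; the argmax is kept, ties going
to the lower band index. The fold assignment is frozen once per run, so the
path is deterministic given the seed. There is no early stopping — the
accuracy-vs-k curve is returned and the user reads off the plateau. The
default criterion classifier is gradient boosting in a cheaper 100-tree
profile; the selection wrapper is classifier-agnostic.

## Synthetic scenes

The generator emulates the structure of calyx-view apple hypercubes:

- **Endmembers** — a smooth quadratic-in-wavelength reflectance baseline
  minus Gaussian absorption valleys at 950, 1200 and 1400 nm (water/CH
  overtones); calyx = healthy × 0.3; background near the dark-current
  level.
- **Infestation** — infested tissue is depressed multiplicatively, with the
  depression weighted by a spectral profile concentrated at the absorption
  valleys plus a flat floor (tissue damage changes water content, so the
  valleys deepen disproportionately). The effect-size scalar is the
  depression at the profile maximum; 1.0 is the exact null. A purely flat
  depression would be removed entirely by max-normalization; the
  valley-weighted form keeps infested spectra below healthy ones at every
  band while a shape difference survives preprocessing. The profile can
  instead be confined to arbitrary narrow bands
  (`infestation_bands`) for recovery experiments.
- **Forward model** — `counts = dark + illumination(λ)·R·gain + noise` with
  a mildly non-flat illumination envelope (so calibration is not a constant
  division), per-pixel scalar gain (path-length proxy, sd 2%), additive
  count noise (1% of full scale) and dark current. The white reference sees
  R = 1, so calibration inverts the model exactly at zero noise.
- **Studies** — default control:infested ratio 1:2 (the underlying rearing
  design); per-apple jitter of geometry and brightness with deterministic
  per-apple seeds spawned from the master seed. Jitter is deliberately
  limited to scalar gain + geometry: per-apple spectral *shape* signatures
  would let a pooled pixel split memorize apple identity, and the null
  experiment is designed to detect exactly that failure mode.

What the generator does **not** emulate: cultivar-specific pigment
chemistry, larval tunnel morphology, specular highlights, spectral smile,
or apple-specific spectral signatures. Passing tests therefore demonstrate
the correctness and statistical sanity of the pipeline, not field
performance on real fruit.

## Canonical experiments and problem sizes

`calyxscan.experiments` pins the study conditions used by the test suite and
`scripts/acceptance.py`:

- **Null / power studies** — 2 control + 2 infested apples at 200×200 px,
  128 bands → ~7.9k ROI pixels, ~2.4k validation pixels. Under the null
  (effect 1.0, balanced groups) validation accuracy must sit inside the 99%
  binomial band around 0.5; under the strong effect (0.85, 1% noise)
  gradient boosting must reach ≥0.95 and at least match LDA. Larger studies
  only add Kennard–Stone runtime without changing the verdicts.
- **Band recovery** — class signal planted in 5 of 128 bands (Gaussian
  width 2.5 nm, well under the 6.3 nm band spacing, so the signal occupies
  exactly five band indices; wider bumps leak most of their energy into
  neighbours and make "recovery" ill-defined). Amplitudes are equalized
  across the five bands (inverse to the local reflectance×illumination
  product) and the effect/noise pair (0.89 / 0.033) puts single-band
  accuracy near 0.78: strong enough that a true band's marginal gain beats
  the maximum of CV noise over ~125 candidate bands at n = 1500 per class,
  weak enough that selection does not saturate after two bands (a saturated
  criterion makes every later pick arbitrary). Recovery runs on
  max-normalized spectra without SG smoothing — a 31-band window would
  smear a 1-band signal across ±15 neighbours, which would test the
  smoother, not the selector — and uses LDA as the criterion classifier
  (the planted signal is linear; the selector itself is
  classifier-agnostic).

## Numerical conventions and degenerate inputs

- Coordinates are (row, col), 0-based, row 0 at top; band axis last.
- Wavelength→band resolution takes the nearest band centre, ties to the
  lower index; targets beyond the grid by more than half the median spacing
  are errors.
- ENVI IO supports bil/bip/bsq interleaves and uint16/float32 payloads;
  cubes are float64 in memory; a wavelength list is required (downstream
  logic is wavelength-addressed, band numbers are never used as a
  fallback).
- Constant images cannot be thresholded (error); empty masks, single-class
  label vectors, all-identical Kennard–Stone inputs and non-positive
  spectra maxima all raise typed errors rather than propagating NaNs.
- Rasterized disk erosion does not compose exactly
  (`B_{r1} ⊕ B_{r2} ⊊ B_{r1+r2}`); iterated erosion is the weaker
  operation, differing from single-shot erosion only in a one-pixel
  boundary ring.

## Known limitations

- Band count, trim window and segmentation wavelength are data/config
  driven; no instrument-specific defaults beyond the 900–1700 nm
  convention.
- The pooled pixel split is optimistic whenever apples carry identifiable
  signatures; a group-by-apple split is the stricter alternative for real
  data.
- PLS-DA uses a fixed 0.5 threshold on the coded response; no probability
  calibration.
- No automatic knee detection on the selection curve; choosing k is left
  to the user.
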