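# Methods

`pomhsi` implements a complete hyperspectral workflow for detecting and
grading impact bruises on fruit (the reference use case is pomegranate,
whose thick leathery rind hides bruises from visual inspection): synthetic
scene generation, reflectance calibration, PCA-based background removal,
ROI spectrum extraction, chemometric preprocessing, informative-band
selection by virtual dimensionality, and feed-forward neural-network
classification. This note records the models, the parameters that matter,
and the design decisions taken where the problem was genuinely open.

## The measurement model

A line-scan hyperspectral camera produces a cube `R(x, y, λ)` of digital
counts: two spatial axes (detector line `x`, translation-stage scan line
`y`) and a spectral axis on a uniform wavelength grid. Two camera profiles
are built in, matching common VNIR and SWIR line-scan units:

| profile | range (nm) | channels | sampling | depth |
|---------|-----------|----------|----------|-------|
| `vnir`  | 400–1000  | 186      | 3.26 nm  | 16 bit |
| `swir`  | 930–2500  | 288      | 5.45 nm  | 16 bit |

Counts are converted to reflectance with the standard white/dark
correction

    ρ_xy(λ) = ρ_ref(λ) · (R_xy(λ) − R_dark(λ)) / (R_ref(λ) − R_dark(λ)),

where `R_ref` is the image of a grey calibration panel of known
reflectivity `ρ_ref` (0.5 for a 50 % panel, treated as spectrally flat by
default; a per-band vector is accepted) and `R_dark` is the frame with the
source off. Because panel and scene share the illumination field, the
correction cancels both the source non-uniformity and the dark current
exactly in the noiseless limit. Near-zero denominators (below a floor of
1 count) are flagged invalid and zeroed rather than propagated as NaN;
reflectances above `clip_max = 1.2` (specular pixels) are clipped, and
both tallies are kept in the cube metadata.

## Synthetic scenes

No public cube archive accompanies the bruise-study design this package
targets, so the generator is a first-class, tested module. Each scene is a
128×128-pixel view (a desk-scale default; the physical cameras have
1800/384-pixel lines) of a fruit disc on a dark background, with an
optional elliptical bruise patch strictly inside the disc. The true
reflectance of each pixel is a linear mixture of three endmembers
(background, sound rind, bruised rind); inside the bruise ellipse a mixing
fraction (default 0.85) interpolates between sound and bruised rind. The
sensor model applies a smooth multiplicative illumination field (tilted
plane plus a broad lobe, ±10 % by default), a gain of 30 000 counts per
unit radiance-equivalent reflectance, a 500-count dark offset, Gaussian
noise of sd 0.02 reflectance units per pixel-band, and 16-bit rounding
with clipping. White and dark reference frames are rendered under the same
illumination; reference noise is reduced by √25, emulating the usual
25-fold frame averaging.

Endmembers are smooth sums of Gaussian bumps on the wavelength grid with
small per-scene amplitude (2 %) and level (3 %) jitter standing in for
biological variation. Bruise severity follows the drop-test design with
three classes — `no_drop`, `drop_60`, `drop_100` (60 cm and 100 cm drops)
— and is encoded spectrally as *deepened water-absorption features*:
Gaussian dips centred on the 970/1450/1940 nm water bands (whichever fall
inside the camera range, width 120 nm), scaled so the band-mean
reflectance of the bruised endmember drops by 0.06 (drop_60) and 0.10
(drop_100) relative to sound rind. This choice is deliberate. Bruised
tissue leaks moisture toward the surface, so its reflectance falls most
where water absorbs; and a spectrally *flat* drop would be removed
entirely by SNV preprocessing (it only shifts the row mean), leaving the
best-practice preprocessing with nothing to classify — an artifact of the
encoding, not of the science. The dip encoding reproduces the empirical
class-mean ordering sound > 60 cm > 100 cm across the SWIR range while
keeping the task non-trivial at the default noise level.

What the generator does *not* emulate: tissue optics (no radiative
transfer), specular glints, translation-stage motion blur, spatial texture
within the rind, and inter-fruit shape variation beyond disc radius and
position jitter. Passing benchmarks on these scenes therefore demonstrate
that the pipeline's statistics behave as designed — not that a given
accuracy will transfer to physical fruit.

## Background removal and ROI spectra

Pixels are scored on the first principal component of the pixel-spectra
cloud (PCA per cube, mean-centered over pixels); Otsu's threshold splits
the scores in two classes, the fruit side being the spatially compact one
(operationally: the class with the smaller fraction of its pixels on the
image border, since the background always reaches the frame edge). The
largest connected component is kept and holes are filled. On default-noise
synthetic scenes this reproduces the ground-truth disc with Jaccard
overlap ≥ 0.95. Each sample's feature vector is the arithmetic mean
spectrum over its region of interest — by default the whole segmented
fruit face (whether the study ROI was the bruise patch or the camera-facing
face is ambiguous; a `bruise_truth` mode uses the generator's bruise mask
instead), excluding calibration-flagged pixels.

## Preprocessing

Seven variants of the spectrum table are supported: raw, SNV, MSC,
detrending (order-2 polynomial in wavelength), continuum removal (division
by the upper convex hull, computed by a monotone-chain upper hull), and
Savitzky–Golay first/second derivatives (window 11; polynomial order 2
resp. 3; derivatives per band index; edges by one-sided polynomial fit).
Parameters follow common chemometric defaults and are configurable. All
transforms are per-row; MSC's default reference is the mean of the rows it
is fit on, so the pipeline fits it on the training partition and reuses it
for held-out rows. The pipeline defaults to SNV; `compare-preprocess`
ranks all seven by downstream test accuracy.

## Band selection (NWHFC)

The number of spectrally distinct endmembers `k` is estimated by the
noise-whitened Harsanyi–Farrand–Chang test: per-band noise variances from
the residuals of regressing each band on all others (the reciprocal
diagonal of the inverse covariance; ridge-stabilised with a reported
jitter when the covariance is ill-conditioned, as happens whenever there
are fewer samples than bands), band-wise whitening, then for each
eigenvalue rank a one-sided Neyman–Pearson test of the difference between
the correlation (non-centered) and covariance eigenvalues at false-alarm
probability `Pf = 1e-3`, using the asymptotic null sd
`sqrt((2/n)(λR² + λK²))`. Monte-Carlo calibration: on pure-noise inputs
(n = 5000, 30 bands) the test returns k = 0 in ≥ 95 % of replicates, and
recovers k = 3 on high-SNR three-endmember mixtures in ≥ 95 %.

`k` informative bands (clipped to [1, 10]; the cap is configurable) are
then chosen from a PCA of the training spectra: for each of the first `k`
components in order, the band with the largest absolute loading, with
collisions falling through to the next-largest unclaimed band and ties
breaking toward the lower band index.

## Classification

The classifier is a two-layer feed-forward network — logistic-sigmoid
hidden layer (width 10) and softmax output — trained by full-batch Adam
(step 0.05) on the cross-entropy of one-hot targets, from seeded
`N(0, 1/fan_in)` initial weights, with inputs standardized by training-set
statistics. Samples are split 70/15/15 (train/validation/test) by a seeded
shuffle, stratified by class while keeping the exact global sizes
(round-half-to-even on train and validation, remainder to test: 90 samples
give 63/14/13). Training stops after 6 consecutive epochs without
validation-loss improvement (or at 1000 epochs) and returns the weights of
the best validation epoch; the test partition is never touched during
training or band selection. One-hot conventions: detection uses
(bruised, no_bruise) so bruised = [1 0]; severity uses
(drop_60, drop_100, no_drop) so a 60 cm drop = [1 0 0]. Five tasks are
exposed: binary detection over all samples, the three pairwise severity
contrasts (SI: 60 cm vs sound, SII: 100 cm vs sound, SIII: 60 vs 100 cm),
and the combined three-class model.

Performance is reported as a confusion matrix (rows: true class, columns:
predicted class) with overall accuracy `100·trace/total`, class error
`100 − accuracy`, and per-class accuracies.

## Numerical and degenerate-input choices

- Rendering, calibration and cube algebra run in float32 (counts are exact
  below 2²⁴); tabular statistics run in float64.
- Constant spectra (SNV), near-zero MSC slopes (|b| < 1e-8) and
  non-positive rows (continuum removal) are excluded with per-row reports
  rather than poisoning the batch; inside the orchestrated pipeline such
  exclusions abort the stage with the sample ids named.
- Degenerate (constant-pixel) cubes yield all-zero PCA scores and a
  segmentation error rather than an arbitrary mask.
- PCA signs are fixed by making each loading's largest-magnitude entry
  positive; argmax tie-breaks are always toward the lower index / earlier
  class.
- The NWHFC noise covariance uses the population (1/n) normalization so
  the estimate is an exact function of the sample moments.

## Problem sizes used in the shipped benchmarks

The end-to-end benchmark runs the default study conditions — 3 classes ×
30 scenes, SWIR profile, 128×128 scenes, shifts 0.06/0.10, noise 0.02 —
over five master seeds, and the separation-monotonicity check adds two
stronger-shift settings (0.09/0.15 and 0.12/0.20) at the same seeds.
Unit tests use 20–64-pixel scenes and ≤ 8-band tables so that every
numerical kernel can be checked against brute-force oracles
(dense eigendecompositions, exhaustive hull chords, per-window polynomial
fits, explicit per-band regressions).

## Known limitations

- The synthetic scenes are radiometrically, not biologically, faithful;
  absolute accuracies on them say nothing quantitative about real fruit.
- NWHFC's k is unreliable when the sample count is far below the band
  count (the ROI-table regime, 63 training spectra × 288 bands); the
  ridge-stabilised estimate then typically saturates and the band cap
  (default 10) governs the model size in practice.
- The ANN is intentionally small and full-batch; it is not meant for
  pixel-level classification of whole cubes.
- Reflectance above 1.2 and sub-floor denominators are clipped/flagged,
  not modelled.
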