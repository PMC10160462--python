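# pomhsi — hyperspectral bruise detection for fruit

Impact bruises are the most common postharvest injury of pomegranate
fruit, and the thick leathery rind hides them from visual inspection long
after the damage is done. `pomhsi` is a tested re-implementation of the
standard hyperspectral-imaging answer to that problem: image the fruit
with a line-scan VNIR (400–1000 nm) or SWIR (930–2500 nm) camera, convert
counts to reflectance, isolate the fruit from the background, reduce each
fruit to one ROI-averaged spectrum, keep only a handful of informative
wavelengths, and grade bruise severity with a small neural network. It is
aimed at postharvest-technology and chemometrics researchers who want the
whole chain — including a synthetic scene generator that makes every stage
testable without camera data.

## The method

1. **Calibration.** Raw counts become reflectance via the white/dark
   correction `ρ_xy(λ) = ρ_ref(λ)·(R_xy − R_dark)/(R_ref − R_dark)`, with
   a 50 % grey panel (`ρ_ref = 0.5`) by default.
2. **Background removal.** Pixels are scored on PC 1 of the pixel-spectra
   PCA; Otsu's threshold plus largest-connected-component and hole filling
   yields the fruit mask. The sample's feature vector is the mean spectrum
   over the mask.
3. **Preprocessing.** Raw, SNV, MSC, detrending, continuum removal, and
   Savitzky–Golay 1st/2nd derivatives; SNV is the default.
4. **Band selection.** The number of spectrally distinct endmembers `k`
   is estimated with the noise-whitened Harsanyi–Farrand–Chang (NWHFC)
   eigenvalue test (Pf = 1e-3); `k` bands are then picked from the
   largest-|loading| bands of the first `k` principal components of the
   training spectra.
5. **Classification.** A two-layer network (sigmoid hidden layer, softmax
   output) on one-hot targets, 70/15/15 train/validation/test split with
   early stopping on the validation loss; performance is reported as a
   confusion matrix with overall accuracy and class error.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

```python
from pomhsi import PipelineConfig, extract_spectrum_table, run_task

config = PipelineConfig(seed=1)           # 3 classes x 30 SWIR scenes
table = extract_spectrum_table(config)    # simulate -> calibrate -> segment -> ROI means
result = run_task(table, "combined", seed=1)

print("NWHFC k:", result.endmember_estimate.k)
print("bands (nm):", [round(w) for w in result.band_set.wavelengths])
print("test accuracy: %.1f%%" % result.test_accuracy)
print(result.report.matrix)
```

prints

```
NWHFC k: 119
bands (nm): [930, 935, 979, 1165, 1171, 1204, 1384, 1570, 1898, 2500]
test accuracy: 92.3%
[[3 1 0]
 [0 4 0]
 [0 0 5]]
```

Read: on 90 synthetic SWIR scenes the NWHFC test saturates in the
few-samples/many-bands regime (63 training spectra × 288 bands), so the
band cap of 10 applies; the selected set includes bands near the 1450 and
1940 nm water-absorption shoulders (1384, 1898 nm) where bruising
expresses; and the held-out test partition (13 fruit, rows/columns in
order drop_60, drop_100, no_drop) is classified at 92.3 % — one 60 cm
drop mistaken for a 100 cm drop — inside the 80–96.7 % severity-accuracy
range such studies report.
The same run from the shell:

```bash
pomhsi run-all --seed 1 --out runs/demo        # all five tasks + artifacts
pomhsi run-all --seed 1 --task detect --out runs/detect_only
```

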