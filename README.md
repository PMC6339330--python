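# mrdenoise

Automatic edge-preserving restoration of brain MR images.

The core is the **collateral filter**: a bilateral-style filter whose range
kernel is complemented by a kernel on the median-filtered image, with a
per-pixel windowed binary entropy of the image/median agreement probability
balancing the two. Around it the package provides:

* **Two backends** — a straightforward reference implementation and a
  tiled/buffered schedule (spatial-weight table, per-apron entropy and blend
  buffers) that is algebraically equivalent (max pixel discrepancy
  < 1e-10·MAX_I) and maps mechanically onto a shared-memory GPU kernel.
* **A 95-entry texture feature bank** — statistical/histogram features,
  8 GLCM features × 4 directions, 11 GLRLM features × 4 directions, 3 Tamura
  features, and 7 noise-level estimators (Laplacian-mask, LoG,
  gradient-masked Laplacian, local-means mode, Rayleigh histogram fit,
  Rayleigh ML, autocorrelation).
* **Feature selection** — paired-t ranking across noise levels (paired on
  anatomy) with a p < 0.05 gate, then sequential forward floating selection
  (SFFS) under a cross-validated classifier criterion.
* **Automatic parameter prediction** — a brute-force PSNR grid search
  producing training targets, and a two-stage network system (noise-class
  classifier routing to per-class parameter regressors; tanh hidden layers,
  linear outputs) trained with Levenberg–Marquardt and early stopping.
* **Quality metrics** — PSNR, SSIM (global and windowed), relative PSNR error.
* **Phantom generator** — seeded brain-like phantoms (tissue classes,
  slice-thickness smoothing, multiplicative bias fields of 0/20/40%, Rician
  noise at 1/3/5/7/9% of MAX_I) standing in for a simulated MR database.

## CLI

The `mrdenoise` entry point has subcommands `phantom`, `features`, `select`,
`optimize`, `train`, `denoise`, `metrics`. A typical round trip:

```bash
# generate a corpus of clean/noisy phantom pairs with a CSV manifest
mrdenoise phantom corpus/ --n-per-cell 12 --size 64 --seed 0

# train the two-stage parameter predictor (brute-forces each pair first)
mrdenoise train corpus/manifest.csv --out model.json --seed 0

# restore an image automatically, with metrics against a clean reference
mrdenoise denoise corpus/phantom_0002_noisy.png --model model.json \
    --out restored.png --clean corpus/phantom_0002_clean.png --report report.json

# or manually, with explicit filter parameters from a YAML config
mrdenoise denoise input.nii --config params.yaml --out restored.nii

# quality metrics between any two images
mrdenoise metrics clean.png restored.png
```

Manual-mode YAML keys: `radius`, `sigma_s`, `sigma_r`, `sigma_m`, `beta`,
`beta_mode` (`scalar` or `adaptive`). Inputs may be 8/16-bit PNG/TIFF slices
or NIfTI volumes (processed slice by slice); outputs are written in the input
format and dtype. `MAX_I` defaults to the dtype maximum and can be overridden
with `--max-intensity`.

## Conventions

* Entropy uses the natural log with 0·log 0 = 0; the ensemble weight
  `W = W_S · W_R^(1/(1+H)) · W_M^H` is evaluated in log space.
* Window radius defaults to 1 (3×3) for both the median filter and the
  collateral window; borders are edge-replicated everywhere.
* `beta` blends input and median image; `adaptive` mode uses
  `beta(x, y) = 1 − p(x, y)`.
* GLCM/GLRLM use min–max quantization to 32 levels; directions are
  0° = (0,+1), 45° = (−1,+1), 90° = (−1,0), 135° = (−1,−1) in row/column
  coordinates. Noise estimates are reported as fractions of MAX_I.
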