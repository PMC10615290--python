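# sparus

Deep-learning-assisted **sparse-array ultrasound imaging** as a reusable,
fully synthetic-data-driven Python package:

- **`sparus.acquisition`** — linear-array geometry (128 elements, 70 µm
  pitch, 28 MHz, 60% bandwidth), aperture decimation (keep-every-k →
  64-channel/140 µm and 16-channel/560 µm sparse arrays), plane-wave
  sequences (7 angles, −15°…15°), and a single-scattering time-of-flight RF
  simulator for point-scatterer phantoms.
- **`sparus.beamform`** — per-angle delay-and-sum with Hanning apodization
  over the active aperture, coherent compounding across angles, envelope
  detection (Hilbert), log compression to 8-bit 512×512 B-mode frames, and
  the closed-form grating-lobe offset predictor.
- **`sparus.restoration`** — a residual U-shaped encoder–decoder
  (Conv–BN–ReLU residual blocks with tensor-addition skips, 2× max pooling,
  sub-pixel/pixel-shuffle upscaling) that restores sparse-array B-mode
  images toward their dense-array ground truth. Implemented in pure NumPy
  with manual backpropagation (Adam, L1 + perceptual loss with a fixed
  seeded feature extractor), HDF5 checkpoints.
- **`sparus.metrics`** — global SSIM (whole-image formula; windowed variant
  optional), MSE, PSNR, FWHM, IoU, Bland–Altman agreement (bias, limits of
  agreement, Pearson r, paired t-test), and noncentral-t power analysis for
  two-sample t-tests.
- **`sparus.phantoms`** — synthetic data: wire targets, tooth/gingiva-like
  layered speckle scenes with exact-by-construction gingival thickness,
  negative controls (vessel/muscle/noise), paired sparse/dense dataset
  assembly with an 80/20 train/validation split, and automated
  2 mm-from-margin perpendicular thickness measurement.
- **`sparus.cli` / `sparus.config`** — validated YAML configuration, a
  five-stage pipeline (simulate → beamform → train → predict → evaluate)
  with a hashed run manifest, and a `sparus` command-line interface.

## CLI

```bash
sparus demo --out runs/demo --n-pairs 60 --epochs 20   # end-to-end small run
sparus simulate  --config cfg.yaml --out runs/x
sparus beamform  --rf rf.h5 --grid grid.yaml --dr 50 --out img.png
sparus train     --data pairs.h5 --config runet.yaml --out model.h5
sparus predict   --model model.h5 --in sparse.png --out pred.png
sparus evaluate  --pairs pairs.h5 --model model.h5 --out metrics.csv
```

## Notes

- The 62.5 MHz DAQ rate quoted for the hardware undersamples the −6 dB
  band edge of a 28 MHz / 60% pulse (36.4 MHz > Nyquist). Simulations that
  assert spectral or beam-pattern properties therefore sample at 250 MHz;
  the physical rate remains the configuration default.
- Sparse apertures deactivate elements on transmit and receive; under the
  idealized plane-wave transmit model the transmit field is
  element-independent, so sparse RF data equal the dense simulation with
  inactive receive rows zeroed (`mask_rf`).
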