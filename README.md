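# blockstorm

Single-molecule localization microscopy (SMLM) through a lossy consumer
camera: simulate dSTORM video as a cellphone sensor and video codec would
record it, calibrate the camera model back out of the footage, and localize
blinking emitters with either a classical fitter or a conditional-GAN
localizer trained on synthetic pairs.

## Why

dSTORM reaches sub-diffraction resolution by imaging sparse, stochastically
blinking fluorophores over thousands of frames and localizing each blink to
nanometer precision. The method normally assumes a scientific camera with
known, well-behaved noise. A phone camera violates every assumption at once:
an opaque image signal processor, unknown gain and offset, early saturation,
and — worst of all — lossy H.264 video compression whose 4×4 block transform
leaves structured artifacts that classical detectors mistake for emitters.

This package models that entire degradation chain and inverts it:

* **camera** — Poisson–Gaussian sensor forward model;
  photon-transfer-curve calibration recovering gain, offset, read noise and
  the end of the linear range from repeated frames; dark-series analysis
  (drift, periodic intensity dips from inter-frame coding).
* **degradation** — a bespoke 4×4 exact-match integer-transform quantizer
  reproducing H.264 blocking artifacts deterministically (lossless at
  quality 100), plus an optional round trip through a real H.264 encoder
  and temporal artifact injection.
* **simulate** — blinking-emitter simulator: Poisson emitter counts at a
  configured density, pixel-integrated Gaussian PSF rendering, sensor and
  compression applied per config, paired with single-pixel localization
  maps on an upsampled grid for training.
* **baseline** — conventional difference-of-Gaussians + threshold +
  pixel-integrated Gaussian least-squares localizer (the classical
  reference, and the thing blocking artifacts fool).
* **nn** — a small NumPy autograd engine, a U-Net generator with
  resize-convolutions and a PatchGAN discriminator, and the composite
  training loss: cross-entropy adversarial term (weight 3, active every
  third iteration after a 1000-iteration warm-up) + PSF-blurred L1 (weight
  100) + sparsity L1 (weight 100).
* **evaluation** — greedy one-to-one ground-truth matching within a radius,
  events-per-area traces, reconstruction rendering, and Fourier ring
  correlation (FRC) resolution at the 1/7 threshold.
* **estimators** — scikit-learn-style facades (`BaselineLocalizer`,
  `GanLocalizer`) with `fit`/`predict`/`get_params`.

## Worked example

Calibrate a simulated phone sensor, train the GAN localizer on degraded
synthetic frames, and score it on held-out data (about 90 s on one CPU):

```python
import dataclasses

import numpy as np

import blockstorm as bs

# --- 1. Calibrate a simulated phone sensor from a short ramp series -------
sensor = bs.load_sensor_preset("huawei_p9_sec53")  # gain 0.69, offset 4.1, rn 2.5
# a photon-transfer series needs a dark region: left quarter at zero flux
ramp = np.tile(np.clip(np.linspace(-45.0, 135.0, 256), 0.0, None), (256, 1))
frames = np.stack([bs.simulate_sensor(ramp, sensor, seed=i) for i in range(10)])
cal = bs.calibrate_mean_variance(frames)
print(f"gain  {cal.gain_est:.3f} e-/ADU   offset {cal.offset_est:.2f} ADU   "
      f"read noise {cal.read_noise_est:.2f} e-")

# --- 2. Simulate a compressed dSTORM acquisition and train the localizer --
cfg = bs.AcquisitionConfig(
    fov=(16, 16), pixel_size=100.0, psf_sigma=130.0,
    density=2.0, n_frames=256, photons_per_emitter=1000.0,
    photon_sigma_log=0.0, upsample=2, sensor=sensor,
    compression=bs.CompressionConfig(quality=90),
)
pairs, _ = bs.make_training_pairs(cfg, seed=100)
model = bs.train(
    pairs,
    bs.GeneratorSpec(depth=3, base_channels=16),
    bs.DiscriminatorSpec(n_layers=2, base_channels=16),
    bs.LossWeights(),                       # lambda_cGAN=3, lambda_L1=100, lambda_L1s=100
    bs.TrainConfig(learning_rate=1e-3, epochs=30, seed=7),
    psf=bs.PsfKernel(sigma=2.6),            # 130 nm PSF on the 50 nm map grid
)
print(f"final blurred-L1 {model.history[-1].l1_psf:.4f}")

# --- 3. Localize held-out frames and score against ground truth -----------
test_pairs, gt = bs.make_training_pairs(dataclasses.replace(cfg, n_frames=200),
                                        seed=900)
maps = bs.infer_stack(model, np.stack([p.x for p in test_pairs]))
detections = bs.maps_to_table(maps, threshold_fraction=0.3,
                              pixel_size=cfg.pixel_size, upsample=cfg.upsample)
_, score = bs.match_events(detections, gt, radius=200.0)
print(f"matched {score.n_matched}/{score.n_gt} events "
      f"({score.matched_fraction:.1%}) at mean error {score.mean_distance:.1f} nm")
```

Output (verbatim; everything is seeded, so it reproduces exactly):

```
gain  0.683 e-/ADU   offset 4.26 ADU   read noise 2.33 e-
final blurred-L1 0.0316
matched 800/977 events (81.9%) at mean error 43.5 nm
```

Four out of five blinks recovered at a 43 nm mean error — from 100 nm
camera pixels and quality-90 compressed, noisy frames, versus a 200 nm-scale
diffraction limit — is the point of the exercise.

## Command line

The `blockstorm` entry point chains the same stages from YAML configs:

```
blockstorm simulate --config run.yaml --out outdir/      # stack + ground truth
blockstorm degrade --input s.tif --out d.tif --quality 80
blockstorm calibrate --input ramp.tif                    # gain/offset/read noise
blockstorm darkstats --input dark.tif                    # drift + dip period
blockstorm localize-classic --input s.tif --out locs.csv
blockstorm train --config run.yaml --out model.npz
blockstorm localize-gan --model model.npz --input s.tif --out locs.csv
blockstorm evaluate --detections locs.csv --ground-truth gt.csv
blockstorm frc --image-a a.tif --image-b b.tif
```

Localization tables use the ThunderSTORM CSV dialect
(`id,frame,x [nm],y [nm],sigma [nm],intensity [photon]`) so they open in
existing SMLM viewers.

## Reproduction

Run the test suite (about 2 minutes on one CPU; the slowest test trains the
GAN localizer end to end):

```
python -m pytest
```

Recompute the headline numbers from scratch:

```
python scripts/acceptance.py --seed 0 --out report.json
```

which simulates, calibrates and evaluates everything anew and writes one
JSON entry per quantity. Reference values and a run at seed 0:

| key | quantity                                   | reference | seed-0 value |
|-----|--------------------------------------------|-----------|--------------|
| t1  | recovered gain (e-/ADU)                    | 0.69      | 0.687        |
| t2  | recovered offset (ADU)                     | 4.1       | 4.257        |
| t3  | recovered read noise (e- RMS)              | 2.5       | 2.359        |
| t4  | recovered end of linear range (ADU)        | 220       | 217.1        |
| t5  | dark-series dip period (s)                 | 1.07      | 1.069        |
| t6  | realized simulator density (emitters/μm²)  | 6.0       | 6.019        |

t1–t4 are tolerated at 10% relative, t6 at 2%; the calibration quantities
are stochastic (different seeds resample the synthetic frames) but stay
well inside tolerance — e.g. seed 123 gives gain 0.689, offset 4.256,
read noise 2.343, linear max 219.5, density 5.990.

See `docs/methods.md` for model definitions, parameter choices and
limitations.
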