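# Methods

Models, assumptions, and the reasoning behind parameter choices. Numeric
behaviour quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing below is an unchecked claim.

## Sensor model (`blockstorm.camera`)

Forward model, per pixel, for an expected photon count `p`:

```
electrons ~ Poisson(qe * p) + Normal(0, read_noise)
ADU       = round(electrons / gain + offset), clipped to [0, min(linear_max, 2^bit_depth - 1)]
```

Assumptions: shot noise and read noise are independent; gain and offset are
spatially uniform (no per-pixel fixed-pattern noise); saturation is a hard
clip at `linear_max`. The shipped `huawei_p9_sec53` preset (gain 0.69
e-/ADU, offset 4.1 ADU, read noise 2.5 e- RMS) describes a phone sensor in
a dim-light video mode.

### Photon-transfer calibration

For repeated frames of a static scene, the temporal variance of a pixel is
linear in its mean with slope `1/gain`, so:

* **gain** = 1 / slope of a robust weighted line fit through the binned
  variance-vs-mean curve (pixels binned by temporal mean; extreme-tail bins
  trimmed because pixels select into them partly by having fluctuated
  there, which biases bin variance).
* **offset** = robust mean of the darkest pixels. This requires the
  calibration series to contain a zero-flux region; the README example and
  the test helpers reserve a quarter of the frame for it.
* **read noise** from the intercept via
  `var = (mean - offset)/gain + rn²/gain² + 1/12`; the `1/12` ADU² term is
  the quantization noise of the rounding step, which matters at read noises
  of a few electrons and sub-unity gains.
* **linear_max**: the linear region is grown bin by bin while the relative
  deviation from the fitted line stays ≤ 20%. A hard clip censors the
  pixel distribution, so the variance sags *before* the clip level; the
  observed variance ratio is inverted through the censored-Gaussian
  variance function to place the breakpoint at the clip level itself
  rather than at the onset of censoring. Without this correction the
  estimate lands roughly one noise sigma low.

Calibration on noiseless (zero-variance) input raises
`CalibrationUndefinedError` rather than returning garbage.

### Dark-series analysis

The per-frame spatial mean is detrended with a least-squares line (slope
reported as drift); the dip period is the smallest significant
autocorrelation peak whose multiples carry the dominant peak (sub-multiple
preference), with significance set at 5× the median absolute deviation of
the autocorrelation over candidate lags. Dips injected every 31st frame at
29 fps are reported as 31 frames = 1.069 s.

## Compression model (`blockstorm.degradation`)

The bespoke degrader applies the 4×4 exact-match integer transform

```
C = [[1, 1, 1, 1], [2, 1, -1, -2], [1, -1, -1, 1], [1, -2, 2, -1]]
```

blockwise (`coeff = C · block · Cᵀ`), quantizes, and inverts exactly
(`C⁻¹ = Cᵀ · diag(1/r²)` with row norms² `r² = (4, 10, 4, 10)`). The
quality-to-step mapping is `q(quality) = max(1, round(2^((100-quality)/12.5)))`
— the step doubles every 12.5 quality points and quality 100 gives `q = 1`.

Two deliberate choices:

* **Quantization acts on normalized coefficients**: the per-coefficient
  step is `q · |r_i||r_j|` (the geometric normalization the integer
  transform folds into its quantization tables). Quantizing the raw
  transform coefficients with a flat step `q` cannot produce blocking
  artifacts at realistic qualities — the effective pixel-domain step would
  be `q/10` to `q/4`, below the noise floor — and blocking is the central
  artifact this model exists to reproduce. With the normalized step, a
  noise-only frame (σ ≈ 1 ADU) acquires a boundary-to-interior gradient
  ratio ≥ 1.07 at quality 80 and ≥ 1.48 at quality 70 (asserted in the
  degradation tests).
* **`q = 1` bypasses quantization entirely**, making quality 100 exactly
  lossless on integer frames (bit-identical round trip, asserted in tests).

The block grid can be offset per frame; the simulator randomizes the offset
so a learned localizer cannot overfit to a fixed grid. A real-codec path
(`encode_decode_video`) round-trips through H.264 via imageio-ffmpeg when
an encoder is installed and raises `CodecUnavailableError` otherwise.
`inject_temporal_artifacts` adds a linear intensity drift and periodic dips
(the signature of inter-frame coding refreshing reference frames).

Limitations: no motion estimation, no entropy coding, no deblocking filter,
no rate control — only the stationary blocking signature of the transform
and the temporal envelope are modelled.

## Blinking simulator (`blockstorm.simulate`)

Per frame, the emitter count is Poisson with mean `density × FOV area`;
positions are uniform over the field; photon counts are log-normal around
the configured mean (σ_log = 0.3 by default, 0 for fixed counts). Frames
are rendered by integrating an isotropic Gaussian PSF over each pixel (erf
differences, exact to machine precision — photon conservation is asserted
to 0.5%). The sensor and compression models above are then applied, and
frames are nearest-neighbour upsampled to the map grid.

Targets for training are *localization maps*: zero everywhere except one
pixel per blink at `floor(position / map_pixel)` on the upsampled grid,
valued at the emitter's photon count. The coordinate convention places the
origin at the outer corner of the first pixel; a map pixel `(r, c)`
converts back to `((c + 0.5)·Δ, (r + 0.5)·Δ)` nm with `Δ = pixel_size /
upsample`.

Realized density self-consistency: at 6 emitters/μm² over 10×10 μm and
2000 frames the realized mean density is within 2% of the configuration
(seed-0 acceptance run: 6.019).

## Baseline localizer (`blockstorm.baseline`)

Difference-of-Gaussians band-pass (scales σ and 2σ), 8-neighbourhood local
maxima above `k · std(filtered frame)`, then least-squares fitting of a
pixel-integrated 2-D Gaussian with bounds checking (fits at the border,
outside plausible PSF widths of 50–400 nm, or non-converged are dropped).
`k = 3` is the conventional artifact-resistant setting; `k = 1` is the
permissive setting used to demonstrate that compressed noise floods a
classical detector with false peaks while the learned localizer stays
quiet (asserted in the artifact-suppression test).

## GAN localizer (`blockstorm.nn`)

A conditional image-to-image GAN translates degraded camera frames
(upsampled to the map grid) into localization maps.

* **Generator**: U-Net, stride-2 4×4 encoder convolutions (LeakyReLU),
  resize-convolution decoder (nearest-neighbour upsample + 3×3 conv) to
  avoid checkerboard artifacts, skip connections at every scale. The
  output head is **linear**; negatives are clipped at inference. With a
  saturating non-negativity activation (ReLU or softplus) the sparse
  targets make the background gradient drive pre-activations deeply
  negative in early training, after which the activation gradient
  vanishes and the model is stuck emitting all-zero maps; a linear head
  keeps the L1 subgradient bounded everywhere and the collapse does not
  occur. The sparsity loss pulls the background to zero from both sides.
* **Discriminator**: PatchGAN over (frame, map) channel pairs — stride-2
  4×4 convolutions and a 3×3 sigmoid head, scoring overlapping patches so
  the adversarial loss is size-agnostic.
* **Loss** (weights configurable, defaults λ_cGAN = 3, λ_L1 = 100,
  λ_L1s = 100):
  * cross-entropy conditional-GAN term, active only every third iteration
    after a 1000-iteration warm-up (localization accuracy is carried by
    the L1 terms; the adversarial term sharpens but destabilizes);
  * L1 between PSF-blurred prediction and PSF-blurred target
    (peak-normalized Gaussian kernel, σ = PSF width on the map grid) —
    blurring gives the loss a capture range beyond one map pixel;
  * L1 sparsity penalty on the raw prediction.
  The reported total is identically `λ_cGAN·L_cGAN + λ_L1·L1 + λ_L1s·L1s`
  (decomposition asserted every iteration in tests).
* **Optimization**: Adam with β₁ = 0.25 (low momentum stabilizes the
  alternating game), β₂ = 0.999. Inputs are normalized by a global
  high-percentile frame scale, targets by their median nonzero value; both
  scales are stored with the model and undone at inference.
* **Inference**: fully convolutional, so any frame size divisible by
  `2^depth` works regardless of training size. `maps_to_table` thresholds
  at a fraction of the frame maximum, groups 8-connected components, and
  takes intensity-weighted centroids.

End-to-end behaviour (asserted, fully seeded): trained on 256 frames at
density 2/μm², 1000 photons/emitter, quality-90 compression (30 epochs,
learning rate 1e-3, ≈ 75 s on one CPU), the localizer recovers 81.9% of
held-out ground-truth events within 200 nm at a 43.5 nm mean error; across
training seeds 7–9 the matched fraction spans 0.795–0.860, against test
bounds of 0.7 and 100 nm.

## Evaluation (`blockstorm.evaluation`)

* **Matching**: greedy one-to-one assignment in ascending distance order
  within a radius (default 200 nm), per frame; equivalent to the
  brute-force optimal-order oracle on small instances (property-tested).
  Reported: matched fraction of ground truth and mean matched distance.
* **FRC**: ring-wise normalized cross-correlation of two independent
  reconstructions' spectra; resolution is the inverse of the first
  crossing below 1/7 (linear interpolation between rings). The
  implementation is validated against an analytic oracle: for two Poisson
  samplings of a common σ-blurred intensity, the expected crossing is
  `f* = sqrt(ln(6k)) / (2π σ_px · pixel_size)` for count scale `k`, and
  the measured crossing is within 15% of it. Split-half FRC requires the
  two halves to share structure; on structureless (uniform-random) data
  the curve correctly hovers near zero.

## Limitations

* The compression model reproduces blocking statistics, not an actual
  bitstream; rate-distortion behaviour of a real encoder will differ in
  detail.
* The sensor model has no fixed-pattern noise, no rolling-shutter effects,
  and treats the in-camera ISP (denoising, demosaicing) as absorbed into
  the effective PSF and noise parameters.
* The autograd engine is NumPy on a single CPU, sized for desk-scale
  training (thousands of 32×32-map iterations in minutes), not for
  production-scale datasets; the architecture supports larger fields but
  wall-clock cost grows accordingly.
* Blinking is memoryless (no fluorophore photokinetics across frames), so
  temporal correlations of real dye blinking are not modelled.
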