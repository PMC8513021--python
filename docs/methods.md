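# Methods

## Problem and model

Green peppers and their foliage are nearly metameric to an RGB camera: both
are green, and the usable class contrast is confined to narrow spectral
features (plausibly driven by differing chlorophyll a/b content, with a
chlorophyll-b absorption feature just below 650 nm).  Rather than
hand-picking an optical filter and then training a segmentation model,
`pepperseg` treats the filter as the first layer of the network and optimizes
both jointly.

The forward model from a hyperspectral radiance cube `R(x, y, λ)` to the
simulated camera image is

1. **Optical filter layer** — `L(x, y, λ) = R(x, y, λ) · T(λ)`, a per-band
   scale applied identically at every pixel (a 1×1 depth-wise convolution
   without bias).  `T` is the learnable transmittance curve, one weight per
   band.
2. **Camera-spectral-response (CSR) layer** — `P_k(x, y) = Σ_i C_k(λ_i)
   L(x, y, λ_i)` for `k ∈ {R, G, B}`, a frozen 1×1 convolution with three
   kernels.  The camera is assumed linear.
3. **Normalization** — `(P − min) / (max − min)`, clipped to `[0, 1]` to
   emulate saturation and dark current, then floored at `ε = 0.01` (add ε,
   re-cap at 1).  The floor guarantees strictly positive channels so the
   ratio denominators below can never vanish.  The clip formula is applied
   *before* the ε shift: scaling and clipping emulate the sensor, the floor
   is purely numerical protection for the ratios.
4. **Color-ratio maps** — nine chromaticity planes
   `d1 = G/(R+G+B)`, `d2 = R/(R+G+B)`, `d3 = B/(R+G+B)`,
   `d4 = G/(G+B)`, `d5 = G/(G+R)`, `d6 = B/(B+R)`,
   `d7 = B/(G+B)`, `d8 = R/(G+R)`, `d9 = R/(R+B)`.
   These are invariant to per-pixel intensity scaling, so they suppress
   illumination and shading variation while preserving chromatic contrast.
   The network input stacks `(R, G, B, d1 … d9)` in that fixed order — 12
   channels (3 in the no-ratio baselines).
5. **Segmentation network** — a U-Net-like encoder–decoder: five encoder
   blocks of (3×3 conv → batch-norm → ReLU) × 2 at widths `b, 2b, 4b, 8b,
   8b` with 2×2 stride-2 max-pools; four decoder stages of 2×2 stride-2
   transposed convolution, skip concatenation with the matching encoder
   block, and a double-conv; final 1×1 convolution and sigmoid.  At the
   reference width `b = 64` a 256×256×12 input has a 16×16×512 bottleneck.
   Convs feeding batch-norm carry no bias.

The loss is `L_total = L_bce + η · L_smooth`, with `L_bce` the mean binary
cross-entropy of the probability map against the mask and
`L_smooth = ‖G W‖²` the squared second differences of the curve (`G` is the
interior (N−2)×N second-difference matrix; rows `1, −2, 1`).  `L_smooth` is
zero iff the curve is affine across bands, and is deliberately not
normalized by N — η absorbs scale.  Physical plausibility is enforced by
projected gradient descent: after every optimizer update the filter weights
are clamped at zero.  There is no upper bound during training; for
fabrication export the curve can be rescaled to unit peak.

## Design choices where the design was open

* **BCE reduction** is the mean over pixels and batch rather than a raw sum,
  so the η grid (0.1, 0.01, 0.001) keeps the same meaning across crop and
  batch sizes.
* **Normalization bounds** `min`/`max` are dataset properties.  They can be
  fixed in the config; by default they are estimated once, before training,
  as the 0.1/99.9 percentiles of raw sensed values over the training cubes
  under the initial filter, and then held constant.  Normalization is global
  (one min/max shared by the three channels); a per-channel mode exists
  behind a flag.
* **Filter initialization** is 0.5 + U(−0.05, 0.05) per band, seeded: a
  symmetric, strictly positive start that leaves every band trainable at
  step 0.
* **Default CSR** is three unit-peak Gaussians (R/G/B peaks 610/540/465 nm,
  σ = 30 nm) — typical silicon-sensor behaviour; a measured curve can be
  supplied as a `wavelength_nm,R,G,B` CSV and is linearly interpolated onto
  the band grid.
* **Learning-rate schedule**: halve on a 5-epoch validation-mIoU plateau,
  floor 1e−5.  Model selection keeps the epoch with the best validation
  mIoU.
* **Metrics aggregation**: dataset-level mIoU/F1 aggregate pixel confusion
  counts over all images; a class absent from both truth and prediction is
  skipped and the mean renormalized.  F1 is reported for the pepper class.
* **Kernel importance** of an input channel is the L1 norm of all
  first-layer kernel taps reading that channel (the filter-pruning
  statistic); conv biases are absent by construction.
* **Experiment arms are flags, not code paths**: (use_filter,
  use_ratio_maps) = (T, T) co-design with ratio maps, (T, F) filter only,
  (F, F) raw camera (filter frozen at all-pass).

## Numerical implementation

The whole chain is differentiated by a small reverse-mode autodiff engine on
NumPy arrays (float64 throughout).  Convolutions are evaluated via im2col +
matmul; the 2×2 stride-2 transposed convolution is an exact block reshape;
max-pool routes gradients to the first maximum in scan order, and batch-norm
uses batch statistics in training and running averages (momentum 0.1) in
evaluation.  Double precision keeps analytic gradients within ~1e−5 of
central finite differences on the smooth parts of the chain; across ReLU /
max-pool kinks the finite-difference comparison itself carries O(h) error,
which is why the full-network check uses a smaller step.

Degenerate inputs: zero-radiance pixels are representable (the ε floor keeps
ratios defined); a non-finite loss aborts training with the offending step
index; mask I/O accepts only 8-bit single-channel PNGs; ENVI reads verify
the value count against the header.

## Synthetic scenes

The scene generator replaces an instrument dataset that is not publicly
available and makes the recovery target *known*:

* both classes share one smooth green-vegetation reflectance template (low
  blue, ~550 nm peak, an absorption dip near 650 nm);
* pepper reflectance is the leaf template scaled by (1 + δ) strictly inside
  a configurable contrast window — the only systematic class difference;
* per-pixel radiance = blackbody-shaped illumination (5500 K, mean 1) ×
  class reflectance × a smooth spatial shading field (two low-frequency
  plane waves, relative amplitude 0.25) × mean-one log-normal noise
  (σ = 0.02);
* peppers are random ellipses (convex blobs) stamped into the mask; an
  optional white-reference patch (reflectance 1, mask 0) mirrors field
  acquisition practice.

What this emulates: spectrally near-identical classes, inconstant
illumination intensity, spatial shading, mild sensor noise.  What it does
not: real leaf optics (no PROSPECT-style model), specular highlights beyond
what saturation clipping emulates, instrument noise signatures, cluttered
canopy geometry.  Passing the recovery checks therefore shows that the
optimization finds a *known planted* spectral window under realistic
nuisance variation — not that it matches any particular field dataset.

## Desk-scale study conditions

The demo study (used by the acceptance checks and `scripts/acceptance.py`)
runs three seeds of three arms on 6/2/2 train/val/test scenes of 64×64 px,
60 bands over 400–700 nm, δ = 0.3 in 630–660 nm: co-design with ratio maps
at η = 0.001 and η = 0.1, and the no-filter baseline.  Training uses the
width-8 network, full-frame 64-px crops with horizontal flips,
16 crops/scene, batch 4, 10 epochs, Adam(lr 5e−3, β = (0.5, 0.999)).  The
learning rate is scaled up from the full-scale default (1e−3) because the
demo takes ~240 optimizer steps rather than thousands, and Adam's
displacement per step is proportional to the rate.  Expected behaviour,
verified by the acceptance suite: the filter stays non-negative after every
step; the η = 0.1 arm ends with the smoother curve; the learned curve
transmits the contrast window ~1.5× more than the rest of the spectrum in
most seeds; and the co-designed arm beats the raw-camera baseline on test
mIoU in most seeds.

## Known limitations

* Bands the CSR barely senses (deep blue here) receive almost no
  segmentation gradient; their weights move only through the smoothness
  term, so the exported curve is physically meaningful mainly where the
  camera is sensitive.
* The full-scale configuration (width 64, 256-px crops, 50 epochs) is
  supported but slow on CPU; the package is written for method verification
  and desk-scale experiments, not production training throughput.
* Non-uniform band grids are accepted by the I/O layer but the smoothness
  penalty assumes index spacing 1; resample to a uniform grid before
  training.
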