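# Methods

## Problem and model

Strain elastography (SE) color-codes tissue stiffness inferred from
deformation under probe compression and is read jointly with the
grayscale B-mode image; hard (suspicious) tissue conventionally renders
blue, soft tissue red/yellow, intermediate green.  This package learns
the mapping from a strained B-mode ROI to the corresponding SE color
image with a conditional GAN, so that an elastography-like overlay can
be produced from conventional ultrasound alone.

The generator is an encoder–decoder translation network operating on
1-channel B-mode input scaled to [-1, 1]:

1. a 7×7 convolution stem (reflection padding, instance norm, ReLU);
2. a **spatial attention** gate — `A = σ(conv7×7([mean_c f; max_c f]))`,
   multiplied into every channel — which lets the network emphasize the
   nodule location early;
3. three stride-2 down-sampling conv blocks (channel width doubling);
4. nine residual blocks in the latent space;
5. one **spatially-adaptive denormalization residual block**: each
   normalization re-modulates the instance-normalized activations with
   spatially varying scale/bias maps,

   `out = γ(PF) · (pf − μ)/(σ + ε) + β(PF)`,

   where μ, σ are the per-sample, per-channel spatial mean and standard
   deviation of the activations `pf`, and γ, β are produced from the
   encoder output `PF` (bilinearly resized to `pf`'s spatial size) by a
   shared 3×3 conv + ReLU followed by one 3×3 conv each.  This re-injects
   the encoder's tissue texture before decoding;
6. three up-sampling blocks (nearest-neighbor ×2 resize followed by a
   3×3 convolution — the resize-convolution form is used instead of a
   transposed convolution to avoid checkerboard artifacts; it has the
   same shape contract);
7. a **channel attention** gate — a bottleneck MLP over global average
   and max pooling with a sigmoid — balancing the output color
   channels;
8. a 7×7 conv head with tanh, producing 3 channels in [-1, 1].

The discriminator is a multiscale patch discriminator (default 2
scales): the condition (B-mode) and candidate (elastogram) are
concatenated on channels, and at each scale a stack of stride-2 4×4
convolutions (instance norm, Leaky-ReLU slope 0.2) emits a grid of
patch logits.  Every discriminator convolution is spectral-normalized:
the matricized kernel is divided by its largest singular value,
estimated by one persistent power-iteration step per forward pass
(warm-started at construction).  Intermediate activations feed the
feature-matching loss.

## Objective

With discriminator scales *i*:

    L = Σᵢ L_GAN(G, Dᵢ) + α Σᵢ L_FM(G, Dᵢ) + β L_color(G(x), y)

- `L_GAN`: sigmoid cross-entropy on the patch logits (the log
  objective); a least-squares variant is selectable for stability.
- `L_FM`: mean L1 between discriminator intermediate activations for
  the real and generated pair, averaged over layers, with the real side
  treated as constant.  Default α = 10.
- `L_color`: both images (mapped to [0, 1]) are Gaussian-blurred
  (default 21×21 kernel, σ = 3 — wide enough to suppress speckle-scale
  texture so only brightness/contrast and the large-scale color
  distribution remain) and compared by the sum of an RMS (Euclidean)
  and a mean-absolute distance.  Both distances are normalized per
  pixel and channel, making the value resolution-independent: two
  uniform images offset by 1 score exactly 2.  Default β = 10.
  The color term is computed once on images, not per scale; summing it
  per scale would only rescale β.
- An optional perceptual term taps five layers of a pluggable feature
  extractor with weights [1/32, 1/16, 1/8, 1/4, 1].  No pretrained
  weights ship with the package; `RandomFeatureExtractor` is a fixed
  seeded random conv stack (synthetic, not pretrained) usable for
  self-contained experiments, and the term is disabled (weight 0)
  unless an extractor is supplied.

Training uses Adam (β₁ = 0.5, β₂ = 0.999) with two time-scale update
rules — generator lr 2·10⁻⁴, discriminator lr 10⁻⁴ — batch size 8 and
1500 epochs at the reference scale; desk-scale runs shrink iterations,
batch, and channel widths through the same configuration surface.
Augmentation fires each op independently with probability 0.5: integer
translation up to ±20 px per axis, horizontal/vertical mirroring, and
rotation up to ±15°, with reflection fill (zero fill would fabricate
dark borders that read as spurious hard tissue) and the identical
transform applied to both images of a pair.  Deterministic inference
(no noise input) makes repeated generation bit-identical.

## Numerical core

No GPU framework is assumed: the networks run on a reverse-mode
autodiff engine over float32 numpy arrays (`aue.nn`), providing 2-D
convolution (kernel-position loop over BLAS tensordots), reflect/zero
padding, pooling, nearest and bilinear resampling, the elementwise and
reduction ops the architecture needs, and Adam.  Gradients of every op
are verified against central finite differences, and convolution
additionally against a nested-loop oracle.  In the SPADE denominator
the standard deviation uses `sqrt(var + 1e-12)` so its gradient is
finite for constant channels; ε = 10⁻⁵ is added to σ per the modulation
formula.  Checkpoints store weights, optimizer moments and the
generator RNG state, so resuming replays the loss log bit-compatibly on
the same platform.

## ROI extraction

Raw SE screenshots hold a grayscale panel and a color panel with a
clinician-drawn green ROI box.  Extraction is (1) a device-specific
fixed-location crop (`DeviceProfile.crop_rect`, 0-based half-open
rectangles) around the color panel, then (2) color-gradient boundary
detection: a pixel is *gray* iff max(R,G,B) − min(R,G,B) ≤ `gray_tol`
(default 16; channel spread is robust to brightness), non-gray pixels
are counted per row, and with forward differences d[i] = c[i+1] − c[i]
the entering boundary is the largest positive difference (earliest tie)
and the leaving boundary the largest negative one at or after it
(latest tie) — tie-breaking widens the ROI rather than truncating it.
The pass repeats on columns of the vertically-cropped sub-image.  The
green box itself counts as color, so the detected rectangle is eroded
by 2 px (configurable).  The B-mode crop is the same rectangle
translated by `DeviceProfile.panel_offset`, which must be measured per
device; there is no universal layout.

## Synthetic phantom

Clinical paired data is private, so the study conditions are emulated
by a phantom: an elliptical nodule (semi-axes 10–30% of the frame,
matching 5–30 mm nodules within a few-cm ROI) of uniform stiffness
drawn from U(0.45, 1.0) in a U(0.2, 0.4) background, with a 2 px linear
boundary ramp (narrow enough to keep the colormap invertible at edges).
The B-mode rendering is an affine stiffness-to-intensity map (harder =
darker by default; slope configurable down to zero so experiments can
test whether the model exploits intensity cues) multiplied by unit-median
log-normal speckle — the simplest standard surrogate for ultrasound
speckle; the phantom aims at plausible texture, not acoustic physics.
The elastogram applies a piecewise-linear RGB colormap anchored at
red(0) → yellow(0.25) → green(0.5) → cyan(0.75) → blue(1), which is
invertible on constant regions to within ±0.02 by nearest-color lookup.
Raw-scan composition places the pair in an 800×555 dual-panel canvas
with a 2 px pure-green ROI box in both panels.

What the phantom does **not** model: real elastogram color noise and
smoothing (no public reference for those appearance statistics exists —
the rendered colors are exact colormap values), probe-pressure
variability, acoustic
shadowing, anisotropy, or multi-device layout variation.  Passing tests
therefore demonstrate that the pipeline is correct and trainable on
controlled data, not that it reaches clinical quality on real scans.

## Evaluation

PSNR uses joint MSE over pixels and channels with MAX = 255 (the
per-channel and joint forms coincide for one channel; the joint form is
the universally comparable one); identical images report an `inf`
sentinel excluded from means.  SSIM uses an 11×11 Gaussian window
(σ = 1.5), k₁ = 0.01, k₂ = 0.03, L = 255, averaged over valid window
positions and channels.  FID fits Gaussians to feature embeddings and
computes ‖μ₁−μ₂‖² + tr(C₁+C₂−2(C₁C₂)^½), clipping the matrix root's
spurious imaginary/negative residuals; the embedding is injected and
never downloaded, so absolute FID values are comparable only within one
extractor.  The five-grade color-dominance score classifies pixels by
argmax RGB channel (yellowish pixels fold into red), takes the blue
fraction inside the nodule mask and in an 8 px dilation ring, and
thresholds at 0.1/0.5/0.9 (configurable); it is an automated surrogate
of clinical SE grading, not a claim of specialist equivalence.

## Scaled problem sizes

The training smoke configuration used by the tests and the acceptance
script is 32 phantom pairs at 64×64, generator/discriminator base width
16, batch 4, 200 iterations — small enough for a single CPU while still
showing a falling reconstruction+color objective and a trained model
whose color-dominance grades agree with the phantom ground truth far
more often than an untrained network's outputs.

## Known limitations

- The engine is CPU-bound; clinical-scale training (hundreds of pairs
  at 256×256, width 64, 1500 epochs) is out of desk reach.
- Internal channel widths follow the pix2pixHD convention (base width
  doubling per down-sampling stage).
- The count of SPADE residual blocks is one (after the nine plain
  residual blocks); both counts are configurable.
- GAN training quality cannot be judged from the loss alone; epoch
  selection by visual inspection is replaced by periodic checkpointing
  plus the automated metric report.
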