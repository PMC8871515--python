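# aue-net

Conditional-GAN synthesis of ultrasound **strain elastography** from
grayscale **B-mode** images.

Strain elastography (SE) color-codes tissue stiffness — soft tissue
red/yellow, intermediate green, hard (suspicious) tissue blue — and
improves the assessment of thyroid nodules, but requires add-on
equipment and experienced operators.  This package implements AUE-net,
an attention-augmented image-to-image translation network that learns
the B-mode → SE mapping from paired examples, together with everything
around it: ROI extraction from raw dual-panel device screenshots, a
synthetic strain-phantom generator with known stiffness ground truth,
the color-distribution loss, and quantitative evaluation
(PSNR/SSIM/FID plus an automated five-grade color-dominance score).
It is aimed at researchers studying elastography synthesis and at
anyone needing a fully self-contained, CPU-only conditional-GAN
pipeline on paired medical images.

## Model

The generator G maps a strained B-mode ROI x to an SE image: a spatial
attention gate, 3 stride-2 down-sampling blocks, 9 residual blocks, one
spatially-adaptive denormalization residual block

    out = γ(PF) · (pf − μ)/(σ + ε) + β(PF)

(μ, σ per-sample/per-channel spatial statistics of the activations pf;
γ, β spatially-varying maps convolved from the encoder features PF),
3 up-sampling blocks, a channel attention gate, and a tanh head.  A
multiscale spectral-normalized patch discriminator D_i scores the
(x, y) pair at each scale i, and G minimizes

    Σᵢ L_GAN(G, Dᵢ) + α Σᵢ L_FM(G, Dᵢ) + β L_color

where L_FM matches discriminator features and L_color is the sum of
RMS and L1 distances between Gaussian-blurred images — a texture-blind
color-distribution penalty.  Training uses Adam (β₁ = 0.5, β₂ = 0.999)
with two time-scale update rules (lr_G = 2·10⁻⁴, lr_D = 10⁻⁴) and
paired augmentation (±20 px translation, mirroring, ±15° rotation).
The networks run on the package's own numpy autograd engine
(`aue.nn`); no GPU framework is required.  See `docs/methods.md` for
the full account.

## Worked example

The estimator is scikit-learn shaped; the `aue` CLI wraps it.  An
end-to-end desk-scale run — simulate phantoms, train, translate held-out
B-modes, evaluate — from Python:

```python
from aue.train import run_pipeline

report = run_pipeline({
    "seed": 1,
    "simulate": {"n": 24, "test_n": 8, "width": 64, "height": 64},
    "train": {"max_iterations": 200, "batch_size": 4, "base_channels": 16,
              "d_base_channels": 16, "blur_kernel": 11},
}, "runs/demo")
print(report["evaluate"])
```

which prints (abridged; ~2 minutes on one CPU):

```
n               8
psnr_mean       16.93 dB
ssim_mean       0.586
fid             0.696
grade_agreement 0.875   (7 of 8 held-out nodules graded like the reference)
```

PSNR/SSIM measure pixel/structural fidelity of the generated
elastograms against the reference renderings; FID compares the two
image distributions in a fixed feature embedding (lower is better;
comparable only within one embedding); grade agreement is the fraction
of held-out nodules whose five-grade color-dominance score (blue
fraction inside the nodule vs. its surround) matches the reference —
the automated analogue of specialist scoring.  At this miniature scale
the model already reproduces the stiffness→color structure; it is not a
clinical-quality model.

Or from the shell:

    aue simulate --n 32 --width 64 --height 64 --seed 1 --out data/
    aue train --dataset data/manifest.json --config train.yaml --out runs/
    aue generate --checkpoint runs/checkpoint_final.npz --in data/ --out gen/
    aue evaluate --generated gen/ --reference data/ --out report.json

`aue preprocess --in scans/ --profile device.yaml --out pairs/` extracts
aligned (B-mode, elastogram) pairs from raw dual-panel screenshots by
fixed-location cropping plus color-gradient boundary detection.

## Layout

    src/aue/nn         numpy autograd engine (tensors, conv, spectral norm, Adam)
    src/aue/phantom    synthetic stiffness maps, B-mode/elastogram rendering,
                       raw dual-panel scan composition, dataset generation
    src/aue/preprocess fixed-location crop + color-gradient ROI extraction
    src/aue/model      generator, multiscale patch discriminator, SPADE, attention
    src/aue/losses     GAN / feature-matching / perceptual / color losses
    src/aue/metrics    PSNR, SSIM, FID, color-dominance grading
    src/aue/estimator  AUENetTranslator (fit / predict / checkpointing)
    src/aue/train      training loop, augmentation, pipeline orchestration
    src/aue/cli        the `aue` command line
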