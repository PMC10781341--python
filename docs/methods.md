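# Methods

## Problem and model

Retinal OCT B-scans carry strong multiplicative speckle, and the lesions
that distinguish choroidal neovascularization (CNV), diabetic macular edema
(DME), and drusen from healthy retina vary widely in size. `msdrcn`
implements a multi-scale denoising residual convolutional network for the
four-class problem: a 50-layer bottleneck residual backbone produces stage
features at strides 4/8/16/32, each stage passes through a denoising and
context subnet, and a top-down fusion block merges the scales before a
single fully connected classifier head.

### Soft-denoising block (SDB)

Speckle-related activations concentrate near zero; useful structure maps to
large activations. The SDB removes the near-zero band with a *learned*
soft threshold. For input `x` (B×C×H×W):

    a   = mean over (H, W) of |x|                      (per sample, channel)
    z   = FC2( ReLU( BN( FC1(a) ) ) )                  (C → C/16 → C)
    τ   = sigmoid(z) ⊙ a
    y   = soft(x, τ) + x,   soft(x, τ) = sign(x)·max(|x| − τ, 0)

Because the sigmoid is strictly inside (0, 1), the threshold always sits
strictly below the channel's mean absolute activation, so the block can
never null an entire channel. Thresholds are per-(sample, channel): the
scalar notation of the underlying formula is interpreted channel-wise,
following the deep residual shrinkage lineage the design derives from.
Numerically, the sigmoid rounds to exactly 1.0 once its input exceeds ~37,
so τ is clamped to the next representable double below `a`, preserving the
strict bound under floating-point rounding (the clamp is inactive in any
realistic weight regime).

The FC stack uses ReLU after FC1 (with a BatchNorm between FC1 and the
activation, as in squeeze-excitation designs) and no activation after FC2
other than the sigmoid that produces the scaling.

### Multi-scale context block (MCB)

A 1×1 Bconv (convolution → batch norm → ReLU) reduces channels to 1/8 of
the input; the reduced tensor splits into 4 equal groups; group *k* passes
a 3×3 Bconv with dilation *k* ∈ {1, 2, 3, 4} and padding *k* (spatial size
preserved; the dilation-4 kernel has a 9×9 receptive footprint); groups are
concatenated, a 1×1 Bconv restores the input width, and a skip connection
adds the block input. With all convolutions zeroed the block is exactly the
identity — the residual sanity property the tests assert.

### Feature fusion block (FFB) with guide attention (GA)

Each scale is projected to a common fusion width (256 by default) by a 1×1
Bconv. The coarsest path passes through unchanged; every other path fuses
with the next-coarser *projected* input:

    GA(x_fine, x_coarse):  u = bilinear-upsample(x_coarse)
                           f = BN(x_fine) ⊙ BN(u)
                           y = BConv3×3(f) + x_fine

The literal (non-cascaded) form is the default — path *i* sees the
projected input *i+1*, not the fused output — because the defining
recurrence bottoms out at the projected coarsest map. An FPN-style cascade
that reuses fused outputs is available behind `ModelConfig.cascaded_fusion`
for comparison. Upsampling is bilinear with half-pixel centers
(align_corners = False), implemented as separable interpolation matrices so
the backward pass is exact transposition.

A note on terminology: descriptions of top-down fusion sometimes call the
spatially smaller, semantically stronger map the "high-resolution" feature.
This package resolves naming by spatial semantics only: `x_coarse` is the
spatially smaller map and is always the one upsampled.

### Head and ablation variants

Each fused map is global-average-pooled; the four pooled vectors are
concatenated (4 × fusion width) and one fully connected layer produces the
logits, so every scale reaches the classifier directly under the literal
fusion form. The variant selector builds the ablation ladder:
`resnet` (backbone + GAP + FC), `resnet+ffb`, `resnet+ffb+mcb`, `ms-drcn`
(adds per-stage SDB at native channels). Subnet placement puts the SDB at
native stage widths and the MCB after the 1×1 projection to the fusion
width; that placement reproduces the published parameter ledger — the
default configuration counts 27.31 M trainable parameters, with the SDB
stack contributing 0.70 M ≈ Σ_c 2c²/16 over stages (256…2048) — whereas
channel-native MCBs would add ~1.6 M and contradict it.

## Engine

No GPU deep-learning framework is assumed: the package ships a compact
reverse-mode autodiff engine on NumPy (`msdrcn.nn`) providing exactly the
operator set the model needs (im2col convolution with stride/padding/
dilation, fused batch norm, max pooling, matrix-based bilinear resizing,
soft thresholding, weighted cross-entropy, SGD with momentum). Every
differentiable operator is verified against central finite differences;
blocks are verified against straight-line reference recomputations that
share no code with the engine. Forward passes in evaluation mode are
deterministic (bitwise repeatable).

## Training recipe

Weighted cross-entropy with inverse-frequency class weights
`w_c = N/(K·n_c)` (balanced data ⇒ all weights 1 ⇒ plain mean loss); SGD
with momentum 0.9 and weight decay 1e-4; batch size 32; learning rate
cosine-annealed per epoch, `lr(t) = lr_min + ½(lr_max − lr_min)(1 +
cos(πt/T))`, no warm restarts. Defaults (50 epochs, 1e-3 → 1e-5) are the
fine-tuning recipe and assume a pretrained backbone; the
`pretrained_backbone` option accepts a local `.npz` weight archive — no
weights ship with the package, and all packaged benchmarks train from
random initialization. Checkpoint selection: best validation accuracy,
ties to the earliest epoch. Augmentation (applied rotate → scale →
brightness → flip; the order is a package choice): rotation ±15°, isotropic
scale ±20 %, brightness ±20 %, horizontal flip p = 0.5. Normalization uses
a scalar mean/std computed over the resized training images in [0, 1].
Validation splits are stratified per class (20 % by default) to preserve
imbalance ratios; patient-aware splitting would require patient metadata
and is out of scope. Training aborts on a non-finite loss; no gradient
clipping.

## Noise model and robustness protocol

OCT speckle is multiplicative; in the log domain it is approximately
Gaussian, and the additive component is negligible. The robustness
benchmark therefore corrupts stored 8-bit test images (before resizing or
normalization, max_val = 255) with either

* Gaussian noise, σ = max_val·10^(−PSNR/20), or
* unit-mean Gaussian speckle `x·m`, σ_m = max_val·10^(−PSNR/20)/rms(x),

so the *expected* MSE — hence expected PSNR = 20·log₁₀(max_val/√MSE) —
equals the requested target; by construction both corruptions have the same
expected MSE at equal target. Calibration is analytic per image, not an
iterative search: over a 224² image the chi-square concentration of the MSE
keeps each realized PSNR within a few hundredths of a dB, and the
set-average converges to the target. No clipping is applied during
corruption (clipping would bias achieved PSNR upward); clipping to
[0, max_val] happens only on 8-bit export, and achieved PSNR is logged
pre-clip. Per-image seeds derive as `seed + index`, so a sweep is exactly
reproducible. The standard sweep evaluates overall accuracy at
35/32/29/26/23/20 dB.

## Phantom generator

The generator exists so every pipeline stage is testable without external
clinical data. It renders 6 stacked reflective bands with sinusoidal
boundaries (band reflectivities fixed, mild per-phantom jitter; the outer
band is the brightest, standing in for the RPE complex) and adds
class-specific lesions: Drusen — 4 Gaussian dome elevations of the outer
band; DME — 3 hypo-reflective elliptical cysts plus 1.3× band thickening;
CNV — one large intraretinal hypo-reflective fluid pocket with a
hyper-reflective scar blob beneath the outer band; Normal — none.
Multiplicative speckle `m ~ N(1, σ²)` is applied last and intensities clamp
to [0, 1]. A binary lesion mask accompanies every image to make Grad-CAM
localization measurable. Geometry is deliberately low-dimensional so the
class signal is carried by lesion morphology rather than texture; the
phantoms do **not** emulate coherent-speckle statistics, A-scan physics,
vessel shadows, or pathology progression, so benchmark results on phantoms
demonstrate that the pipeline learns and localizes designed lesion
morphology under multiplicative noise — not clinical-grade accuracy.

A five-feature baseline (band thickness, dark-blob count, bright-blob area,
outer-band bump count, intensity variance) with a random forest separates
held-out phantoms at >0.95 accuracy, confirming the classes are learnably
distinct by design.

## Desk benchmark sizes

All packaged benchmarks run on CPU, so sizes are chosen for minutes, not
hours (stated here as the package's benchmark definition): phantoms
rendered at 64×64 with speckle σ = 0.3; the slim `desk_config` architecture
(stage widths 64/128/256/512, fusion width 64, one bottleneck per stage,
input 64) trained for 10 epochs on 200 train / 50 validation per class with
`lr` 0.01 → 1e-4 (from-scratch setting, chosen a priori; the 1e-3 default
is a fine-tuning rate). This run reaches ≥ 0.9 validation accuracy. The
3-seed directional comparison of the full model against the plain backbone
under 20 dB speckle uses 100/25 per class and 6 epochs. The full-size
default architecture (27.31 M parameters) is exercised for shape/parameter
contracts and single forward passes only.

A caveat on the directional comparison: at 20 dB the corruption is far
outside the training distribution and both variants lose most of their
accuracy, so the ordering between them carries large seed-to-seed variance.
On the packaged benchmark (its fixed dataset and model seeds) the full
model's median accuracy is at least the backbone's, but across other
dataset seeds the sign can flip — at desk scale the denoising advantage is
within seed noise, and the comparison should be read as a protocol
demonstration, not as evidence of a robust effect at this scale.

## Numerical and degenerate-case conventions

* Soft threshold at the boundary |x| = τ maps to 0 (closed band), and the
  subgradient there is taken as 0.
* PSNR of identical images is +inf; `max_val` defaults to 255 in the 8-bit
  domain and 1.0 for normalized arrays.
* Precision (and F1) for a class that receives no predictions is reported
  as 0 with a warning; AUC for a class absent from the truth is reported
  missing (NaN) — conventions chosen because they are conservative.
* Per-class "accuracy" is one-vs-rest binary accuracy (TP+TN)/N, which is
  why per-class accuracies exceed overall accuracy on imbalanced data.
* Batch norm uses momentum 0.1 and eps 1e-5; running variance is the
  unbiased estimate, normalization uses the biased one.
* Grad-CAM maps that are identically zero (e.g. a constant-logit model)
  are returned as zero rather than normalized.
* Bilinear resizing everywhere (augmentation is nearest-padded affine)
  uses half-pixel centers with edge clamping.

## Known limitations

* Training at the published scale (84k images, 224², 50 epochs) is out of
  reach of the NumPy engine; published headline accuracies are not
  reproduced, only the architecture's contracts and the desk-scale
  behaviour of the method.
* The phantom domain is far easier than clinical OCT; accuracy numbers on
  phantoms are benchmark properties of the pipeline, not clinical claims.
* Single-threaded CPU training only; no mixed precision, no distributed
  mode, no hyperparameter search.
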