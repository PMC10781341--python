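# msdrcn

Multi-scale denoising residual convolutional network for classifying
retinal OCT B-scans into **CNV / DME / Drusen / Normal**, for researchers
studying noise-robust OCT image analysis. The package implements the full
architecture and training/evaluation protocol as a tested library plus CLI,
together with a synthetic retinal-phantom generator so everything runs on a
laptop CPU with no external clinical datasets.

## The model

A 50-layer bottleneck residual backbone (`y = f(x, w) + x`) emits four
stage features at strides 4/8/16/32. Each stage feeds a subnet of two
bespoke blocks, and a fusion block merges the scales:

* **Soft-denoising block (SDB).** Speckle maps to near-zero activations;
  the SDB removes them with a *learned* soft threshold. With
  `a = mean_{H,W} |x|` per (sample, channel):

  `τ = sigmoid(FC₂(ReLU(BN(FC₁(a))))) ⊙ a`,
  `y = sign(x)·max(|x| − τ, 0) + x`.

  The sigmoid keeps `0 ≤ τ < mean|x|` strictly, so no channel is ever
  nulled outright.
* **Multi-scale context block (MCB).** 1×1 Bconv reduces channels to 1/8,
  four equal groups pass 3×3 Bconvs with dilations 1–4 (padding = dilation),
  groups concatenate, a 1×1 Bconv restores the width, plus a residual skip.
* **Feature fusion block (FFB) with guide attention (GA).** Every scale is
  projected to 256 channels; each path is fused with the upsampled
  next-coarser map by `y = BConv₃ₓ₃(BN(x_fine) ⊙ BN(up(x_coarse))) + x_fine`.

The head concatenates the global-average-pooled fused maps into one FC
layer. Variants `resnet`, `resnet+ffb`, `resnet+ffb+mcb`, `ms-drcn` build
the ablation ladder. The default configuration has **27.31 M** trainable
parameters, of which the SDB stack contributes 0.70 M.

Training follows weighted cross-entropy (`w_c = N/(K·n_c)`), SGD with
momentum 0.9 and weight decay 1e-4, and a per-epoch cosine-annealed
learning rate `lr(t) = lr_min + ½(lr_max − lr_min)(1 + cos(πt/T))`.

The noise-robustness benchmark corrupts stored test images with Gaussian
noise or multiplicative speckle (`f = x·m`, `m ~ N(1, σ_m²)`), analytically
calibrated so the expected PSNR = `20·log₁₀(Max/√MSE)` hits targets of
35…20 dB, and reports overall accuracy per level. Grad-CAM heatmaps
localize the evidence for each prediction.

Everything runs on a compact NumPy reverse-mode autodiff engine bundled as
`msdrcn.nn` (gradient-checked conv/batch-norm/pooling/resampling ops) — no
GPU framework required.

## Worked example

```python
import numpy as np
from msdrcn import (build_ms_drcn, desk_config, generate_dataset,
                    stratified_split, robustness_sweep)
from msdrcn.training import desk_train_config, train

manifest = generate_dataset(250, "phantoms", global_seed=0,
                            speckle_sigma=0.3, height=64, width=64)
train_m, val_m = stratified_split(manifest, 0.2, seed=0)
model = build_ms_drcn(desk_config(seed=0), "ms-drcn")
result = train(model, train_m, val_m, desk_train_config(epochs=10, seed=0))
print("best val acc:", max(result.history.val_accuracy))
table = robustness_sweep(result.model, val_m, "speckle", [35.0, 20.0],
                         seed=7, mean=result.mean, std=result.std)
print(table)
```

prints (timings aside):

```
epoch   0  lr 1.00e-02  train loss 1.4197 acc 0.258  val loss 1.5459 acc 0.265
...
epoch   9  lr 3.42e-04  train loss 0.1587 acc 0.971  val loss 0.1311 acc 0.970
best val acc: 0.98
[(35.0, 0.975), (20.0, 0.68)]
```

— the model reaches 98 % validation accuracy on the phantom benchmark in
ten epochs, keeps 97.5 % under mild (35 dB) speckle and drops to 68 % at
the heaviest (20 dB) corruption level. (Accuracy at the lowest PSNRs
varies considerably with the seed; see `docs/methods.md`.)

The same flows are available from the shell:

```bash
msdrcn phantom --n-per-class 250 --size 64 --seed 0 --out phantoms
msdrcn train --data phantoms --preset desk --epochs 10 --out run
msdrcn eval  --checkpoint run/checkpoints/best.npz --data phantoms --out run/reports
msdrcn sweep --checkpoint run/checkpoints/best.npz --data phantoms --out run/reports
msdrcn gradcam --checkpoint run/checkpoints/best.npz --data phantoms --out run/figures
```

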