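"""MS-DRCN: multi-scale denoising residual convolutional network.

The model classifies grayscale retinal OCT B-scans into four classes
(CNV, DME, Drusen, Normal).  A 50-layer bottleneck residual backbone yields
four stage features at strides 4/8/16/32.  Each stage feeds a subnet:

* **Soft-denoising block (SDB)** — learns a per-(sample, channel) shrinkage
  threshold: the channel-wise mean of ``|x|`` passes through a two-layer
  bottleneck FC stack and a sigmoid, giving a scaling in (0, 1); the
  threshold is that scaling times mean ``|x|``, so it is always non-negative
  and strictly below the channel's mean magnitude.  The soft-thresholded
  feature is added back to the input (residual shrinkage).
* **Multi-scale context block (MCB)** — a 1x1 Bconv reduces channels to 1/8,
  the reduced feature splits into four equal groups, each filtered by a 3x3
  Bconv with dilation 1/2/3/4 (padding = dilation, so spatial size is kept),
  the groups concatenate, a 1x1 Bconv restores the width, and a skip
  connection adds the block input.
* **Feature fusion block (FFB)** — 1x1 convolutions bring every scale to a
  common width (256 by default); **guide attention (GA)** fuses each scale
  with the next-coarser one: the coarser map is bilinearly upsampled, both
  maps are batch-normalized and multiplied elementwise, a 3x3 Bconv produces
  the modulated feature, and the fine input is added back.

The classification head global-average-pools each fused map, concatenates,
and applies a single fully connected layer.  Ablation variants build the
plain backbone, backbone+FFB, backbone+FFB+MCB, or the full model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

VARIANTS = ("resnet", "resnet+ffb", "resnet+ffb+mcb", "ms-drcn")

DEFAULT_CLASSES = ("CNV", "DME", "Drusen", "Normal")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``stage_channels`` are the bottleneck-stage output widths;
    ``fusion_channels`` is the common width all scales are projected to
    before fusion; ``sdb_reduction`` is the FC bottleneck ratio inside the
    soft-denoising block (hidden width = C / 16 by default);
    ``mcb_reduction`` is the channel reduction inside the multi-scale
    context block (1/8 by default) whose reduced width splits into
    ``mcb_group_count`` dilated groups.
    """

    num_classes: int = 4
    stage_channels: tuple[int, ...] = (256, 512, 1024, 2048)
    fusion_channels: int = 256
    sdb_reduction: int = 16
    mcb_reduction: int = 8
    mcb_group_count: int = 4
    mcb_dilations: tuple[int, ...] = (1, 2, 3, 4)
    input_size: int = 224
    in_channels: int = 1
    pretrained_backbone: bool | str = False
    blocks_per_stage: tuple[int, ...] = (3, 4, 6, 3)
    cascaded_fusion: bool = False
    seed: int = 0

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        self.mcb_dilations = tuple(self.mcb_dilations)
        self.blocks_per_stage = tuple(self.blocks_per_stage)
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")
        if len(self.stage_channels) != 4:
            raise ValueError("stage_channels must list 4 stages")
        if any(b <= a for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ValueError("stage_channels must be strictly increasing")
        if len(self.mcb_dilations) != self.mcb_group_count:
            raise ValueError("mcb_dilations length must equal mcb_group_count")
        if self.fusion_channels % (self.mcb_reduction * self.mcb_group_count):
            raise ValueError(
                "fusion_channels must be divisible by mcb_reduction * "
                f"mcb_group_count (= {self.mcb_reduction * self.mcb_group_count})")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32 (stride stack)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def desk_config(**overrides) -> ModelConfig:
    """Slim configuration used by the CPU desk benchmark (64x64 inputs)."""
    base = dict(stage_channels=(64, 128, 256, 512), fusion_channels=64,
                input_size=64, blocks_per_stage=(1, 1, 1, 1))
    base.update(overrides)
    return ModelConfig(**base)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class SoftDenoiseBlock(nn.Module):
    """Residual shrinkage with a learned per-(sample, channel) threshold."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.bn = nn.BatchNorm1d(hidden)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def threshold(self, x: Tensor) -> Tensor:
        """Per-(sample, channel) threshold, shape (B, C).

        tau = sigmoid(FC2(relu(BN(FC1(a))))) * a with a = mean over (H, W)
        of |x|; the sigmoid keeps tau strictly inside [0, mean|x|).  Because
        sigmoid rounds to exactly 1.0 for large logits in floating point,
        tau is additionally clamped to the next representable value below a,
        preserving the strict upper bound numerically.
        """
        if x.shape[1] != self.channels:
            raise ValueError(
                f"SDB built for {self.channels} channels, got {x.shape[1]}")
        a = nn.mean(nn.absolute(x), axis=(2, 3))  # (B, C)
        z = self.fc2(nn.relu(self.bn(self.fc1(a))))
        tau = nn.mul(nn.sigmoid(z), a)
        return nn.minimum(tau, nn.Tensor(np.nextafter(a.data, 0.0)))

    def forward(self, x: Tensor) -> Tensor:
        tau = self.threshold(x)
        tau4 = nn.reshape(tau, (x.shape[0], x.shape[1], 1, 1))
        return nn.add(nn.soft_threshold(x, tau4), x)


class MultiScaleContextBlock(nn.Module):
    """Dilated group context aggregation with a residual skip."""

    def __init__(self, channels: int, reduction: int = 8, groups: int = 4,
                 dilations: tuple[int, ...] = (1, 2, 3, 4),
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % (reduction * groups):
            raise ValueError(
                f"MCB needs channels divisible by reduction*groups "
                f"(= {reduction * groups}); got {channels}")
        reduced = channels // reduction
        self.group_width = reduced // groups
        self.reduce = nn.BConv(channels, reduced, 1, rng=rng)
        self.branches = [
            nn.BConv(self.group_width, self.group_width, 3, padding=d,
                     dilation=d, rng=rng)
            for d in dilations
        ]
        self.expand = nn.BConv(reduced, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        r = self.reduce(x)
        outs = []
        for i, branch in enumerate(self.branches):
            lo = i * self.group_width
            group = r[:, lo:lo + self.group_width]
            outs.append(branch(group))
        merged = nn.concat(outs, axis=1)
        return nn.add(x, self.expand(merged))


class GuideAttention(nn.Module):
    """Top-down fusion: upsample, normalize, gate multiplicatively, refine."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.bn_fine = nn.BatchNorm2d(channels)
        self.bn_coarse = nn.BatchNorm2d(channels)
        self.refine = nn.BConv(channels, channels, 3, padding=1, rng=rng)

    def forward(self, x_fine: Tensor, x_coarse: Tensor) -> Tensor:
        if x_fine.shape[1] != x_coarse.shape[1]:
            raise ValueError("guide attention requires equal channel counts")
        H, W = x_fine.shape[2], x_fine.shape[3]
        if H % x_coarse.shape[2] or W % x_coarse.shape[3]:
            raise ValueError("upsample ratio between scales must be integer")
        up = nn.upsample_bilinear(x_coarse, H, W)
        f = nn.mul(self.bn_fine(x_fine), self.bn_coarse(up))
        return nn.add(self.refine(f), x_fine)


class FeatureFusionBlock(nn.Module):
    """Project every scale to a common width, then fuse top-down with GA.

    In the literal (default) form each output fuses its input with the
    *projected* next-coarser input; the ``cascaded`` flag switches to
    FPN-style reuse of the already-fused coarser output.
    """

    def __init__(self, in_channels: tuple[int, ...], fusion_channels: int,
                 cascaded: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        self.project = [nn.BConv(c, fusion_channels, 1, rng=rng)
                        for c in in_channels]
        self.ga = [GuideAttention(fusion_channels, rng=rng) for _ in range(3)]
        self.cascaded = cascaded

    def forward(self, stage_features: list[Tensor]) -> list[Tensor]:
        if len(stage_features) != 4:
            raise ValueError("feature fusion expects exactly 4 scales")
        for a, b in zip(stage_features, stage_features[1:]):
            if a.shape[2] != 2 * b.shape[2] or a.shape[3] != 2 * b.shape[3]:
                raise ValueError("scale spatial sizes must halve along the list")
        p = [proj(f) for proj, f in zip(self.project, stage_features)]
        ys = [None, None, None, p[3]]
        for i in (2, 1, 0):
            coarser = ys[i + 1] if self.cascaded else p[i + 1]
            ys[i] = self.ga[i](p[i], coarser)
        return ys


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    """1x1 -> 3x3 -> 1x1 bottleneck residual block."""

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        width = out_channels // 4
        self.conv1 = nn.Conv2d(in_channels, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_channels, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.down_conv = nn.Conv2d(in_channels, out_channels, 1,
                                       stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_channels)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        h = nn.relu(self.bn1(self.conv1(x)))
        h = nn.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(nn.add(h, shortcut))


class ResNetBackbone(nn.Module):
    """Bottleneck residual backbone emitting four stage features."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        stem_ch = config.stage_channels[0] // 4
        self.stem_conv = nn.Conv2d(config.in_channels, stem_ch, 7, stride=2,
                                   padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_ch)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stages = []
        in_ch = stem_ch
        for i, (out_ch, n_blocks) in enumerate(
                zip(config.stage_channels, config.blocks_per_stage)):
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and i > 0) else 1
                blocks.append(Bottleneck(in_ch, out_ch, stride, rng=rng))
                in_ch = out_ch
            self.stages.append(nn.Sequential(*blocks))

    def forward(self, x: Tensor) -> list[Tensor]:
        h = self.pool(nn.relu(self.stem_bn(self.stem_conv(x))))
        feats = []
        for stage in self.stages:
            h = stage(h)
            feats.append(h)
        return feats


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class MSDRCN(nn.Module):
    """Assembled network; ``variant`` selects the ablation configuration."""

    def __init__(self, config: ModelConfig, variant: str = "ms-drcn"):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        if config.pretrained_backbone:
            path = config.pretrained_backbone
            if not (isinstance(path, str) and Path(path).exists()):
                raise ValueError(
                    "pretrained_backbone requires a local .npz weight archive "
                    "path; no weight file is bundled with this package")
        self.config = config
        self.variant = variant
        rng = np.random.default_rng(config.seed)
        self.backbone = ResNetBackbone(config, rng)
        self.use_ffb = variant != "resnet"
        self.use_mcb = variant in ("resnet+ffb+mcb", "ms-drcn")
        self.use_sdb = variant == "ms-drcn"
        fc = config.fusion_channels
        if self.use_sdb:
            self.sdb = [SoftDenoiseBlock(c, config.sdb_reduction, rng=rng)
                        for c in config.stage_channels]
        if self.use_mcb:
            self.proj = [nn.BConv(c, fc, 1, rng=rng) for c in config.stage_channels]
            self.mcb = [MultiScaleContextBlock(fc, config.mcb_reduction,
                                               config.mcb_group_count,
                                               config.mcb_dilations, rng=rng)
                        for _ in config.stage_channels]
        if self.use_ffb:
            ffb_in = (fc,) * 4 if self.use_mcb else config.stage_channels
            self.ffb = FeatureFusionBlock(ffb_in, fc, config.cascaded_fusion,
                                          rng=rng)
            self.head = nn.Linear(4 * fc, config.num_classes, rng=rng)
        else:
            self.head = nn.Linear(config.stage_channels[-1], config.num_classes,
                                  rng=rng)
        if isinstance(config.pretrained_backbone, str) and config.pretrained_backbone:
            state = dict(np.load(config.pretrained_backbone))
            self.backbone.load_state_dict(state)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_with_features(x)[0]

    def forward_with_features(self, x: Tensor) -> tuple[Tensor, dict[str, Tensor]]:
        """Run the network, also returning named intermediate feature maps."""
        if x.ndim != 4:
            raise ValueError("input must be (B, C, H, W)")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial size must be divisible by 32")
        feats: dict[str, Tensor] = {}
        stages = self.backbone(x)
        for i, s in enumerate(stages):
            feats[f"stage{i + 1}"] = s
        h = stages
        if self.use_sdb:
            h = [blk(f) for blk, f in zip(self.sdb, h)]
            for i, f in enumerate(h):
                feats[f"denoised{i + 1}"] = f
        if self.use_mcb:
            h = [mcb(proj(f)) for mcb, proj, f in zip(self.mcb, self.proj, h)]
            for i, f in enumerate(h):
                feats[f"context{i + 1}"] = f
        if self.use_ffb:
            fused = self.ffb(h)
            for i, f in enumerate(fused):
                feats[f"fused{i + 1}"] = f
            pooled = nn.concat([nn.global_avg_pool(f) for f in fused], axis=1)
        else:
            pooled = nn.global_avg_pool(stages[-1])
        logits = self.head(pooled)
        return logits, feats

    def feature_names(self) -> list[str]:
        names = [f"stage{i}" for i in (1, 2, 3, 4)]
        if self.use_sdb:
            names += [f"denoised{i}" for i in (1, 2, 3, 4)]
        if self.use_mcb:
            names += [f"context{i}" for i in (1, 2, 3, 4)]
        if self.use_ffb:
            names += [f"fused{i}" for i in (1, 2, 3, 4)]
        return names


def build_ms_drcn(config: ModelConfig | None = None,
                  variant: str = "ms-drcn") -> MSDRCN:
    """Construct the network (or one of its ablation variants)."""
    return MSDRCN(config or ModelConfig(), variant)


def count_parameters(model: nn.Module) -> int:
    """Total element count over all trainable weight arrays."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MSDRCN, path: str | Path,
                    classes: tuple[str, ...] = DEFAULT_CLASSES,
                    extra: dict | None = None) -> Path:
    """Write weights (.npz) plus a self-describing JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "config": model.config.to_dict(),
        "variant": model.variant,
        "classes": list(classes),
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path) -> tuple[MSDRCN, list[str]]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    model = MSDRCN(ModelConfig.from_dict(sidecar["config"]), sidecar["variant"])
    with np.load(path) as archive:
        model.load_state_dict(dict(archive))
    return model, sidecar["classes"]
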