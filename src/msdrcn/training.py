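"""Training loop: weighted cross-entropy, SGD + momentum, cosine annealing.

The recipe follows the standard OCT-classification protocol: 50 epochs,
batch size 32, SGD with momentum 0.9 and weight decay 1e-4, learning rate
cosine-annealed from 1e-3 to 1e-5 (those defaults suit fine-tuning a
pretrained backbone; short from-scratch desk runs use a larger lr_max).
Class imbalance is handled by inverse-frequency weights in the loss.  The
checkpoint with the best validation accuracy is retained, ties broken by the
earliest epoch.  All randomness (shuffling, augmentation) derives from the
config seed.
"""

from __future__ import annotations

import csv
import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .architecture import MSDRCN, ModelConfig, build_ms_drcn, save_checkpoint
from .data import (AugmentationPolicy, DatasetManifest, augment, class_weights,
                   load_image, normalization_stats, preprocess)


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr_max: float = 1e-3
    lr_min: float = 1e-5
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    variant: str = "ms-drcn"
    use_class_weights: bool = True
    pretrained: bool = False

    def __post_init__(self):
        if not 0 < self.lr_min < self.lr_max:
            raise ValueError("need 0 < lr_min < lr_max")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    best_epoch: int = -1

    def save_csv(self, path: str | Path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "lr", "train_loss", "train_acc",
                             "val_loss", "val_acc"])
            for i in range(len(self.train_loss)):
                writer.writerow([i, self.learning_rate[i], self.train_loss[i],
                                 self.train_accuracy[i], self.val_loss[i],
                                 self.val_accuracy[i]])


def cosine_lr(t: int, T: int, lr_max: float, lr_min: float) -> float:
    """Cosine-annealed learning rate after t completed epochs of T total.

    lr(t) = lr_min + (lr_max - lr_min) * (1 + cos(pi t / T)) / 2; exactly
    lr_max at t = 0 and lr_min at t = T.
    """
    if T < 1 or not 0 <= t <= T:
        raise ValueError("need 0 <= t <= T with T >= 1")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / T))


def desk_train_config(epochs: int = 10, seed: int = 0, **kwargs) -> TrainConfig:
    """Training settings for the CPU desk benchmark.

    Short from-scratch runs use a larger peak learning rate (0.01, annealed
    to 1e-4) than the transfer-learning default, which assumes a pretrained
    backbone and 50 epochs.
    """
    return TrainConfig(epochs=epochs, lr_max=0.01, lr_min=1e-4,
                       seed=seed, **kwargs)


@dataclass
class TrainResult:
    model: MSDRCN
    history: TrainHistory
    mean: float
    std: float
    checkpoint_path: Path | None = None


def _load_all(manifest: DatasetManifest) -> list[np.ndarray]:
    return [load_image(p) for p, _ in manifest.records]


def _evaluate(model: MSDRCN, images: list[np.ndarray], labels: np.ndarray,
              size: int, mean: float, std: float, batch_size: int,
              weights: np.ndarray | None) -> tuple[float, float]:
    """(loss, accuracy) over a preprocessed-on-the-fly image list."""
    model.eval()
    losses, hits, n = 0.0, 0, len(images)
    with nn.no_grad():
        for lo in range(0, n, batch_size):
            batch = images[lo:lo + batch_size]
            x = np.stack([preprocess(im, size, mean, std) for im in batch])
            logits = model(nn.Tensor(x))
            yb = labels[lo:lo + batch_size]
            loss = nn.cross_entropy(logits, yb, weights)
            losses += loss.item() * len(batch)
            hits += int((logits.data.argmax(axis=1) == yb).sum())
    return losses / n, hits / n


def train(model: MSDRCN, train_manifest: DatasetManifest,
          val_manifest: DatasetManifest, config: TrainConfig,
          policy: AugmentationPolicy | None = None,
          out_dir: str | Path | None = None,
          verbose: bool = True) -> TrainResult:
    """Run the optimization loop and return the best-validation model."""
    if len(train_manifest) == 0 or len(val_manifest) == 0:
        raise ValueError("train and validation manifests must be nonempty")
    policy = policy if policy is not None else AugmentationPolicy()
    size = model.config.input_size
    mean, std = normalization_stats(train_manifest, size)
    train_images = _load_all(train_manifest)
    val_images = _load_all(val_manifest)
    y_train = train_manifest.labels_as_indices()
    y_val = val_manifest.labels_as_indices()
    counts = [train_manifest.counts[c] for c in train_manifest.classes]
    weights = class_weights(counts) if config.use_class_weights else None

    opt = nn.SGD(model.parameters(), lr=config.lr_max, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_acc, best_state = -1.0, None
    n = len(train_images)
    for epoch in range(config.epochs):
        t0 = time.time()
        opt.lr = cosine_lr(epoch, config.epochs, config.lr_max, config.lr_min)
        order = rng.permutation(n)
        model.train()
        epoch_loss, epoch_hits = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xs = []
            for j in idx:
                aug_seed = (config.seed * 1000003 + epoch * 10007 + int(j)) % (2**31)
                im = augment(train_images[j], policy, rng_seed=aug_seed)
                xs.append(preprocess(im, size, mean, std))
            x = nn.Tensor(np.stack(xs))
            yb = y_train[idx]
            logits = model(x)
            loss = nn.cross_entropy(logits, yb, weights)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
            epoch_hits += int((logits.data.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _evaluate(model, val_images, y_val, size, mean, std,
                                      config.batch_size, weights)
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(epoch_hits / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(opt.lr)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
            history.best_epoch = epoch
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  "
                  f"train loss {history.train_loss[-1]:.4f} "
                  f"acc {history.train_accuracy[-1]:.3f}  "
                  f"val loss {val_loss:.4f} acc {val_acc:.3f}  "
                  f"[{time.time() - t0:.1f}s]")
    model.load_state_dict(best_state)
    checkpoint_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        checkpoint_path = save_checkpoint(
            model, out_dir / "best.npz", classes=train_manifest.classes,
            extra={"norm_mean": mean, "norm_std": std,
                   "train_config": asdict(config)})
        history.save_csv(out_dir / "history.csv")
        (out_dir / "train_config.json").write_text(
            json.dumps(asdict(config), indent=2))
    return TrainResult(model, history, mean, std, checkpoint_path)


def train_variant(variant: str, train_manifest: DatasetManifest,
                  val_manifest: DatasetManifest, model_config: ModelConfig,
                  config: TrainConfig, **kwargs) -> TrainResult:
    """Convenience: build an ablation variant and train it."""
    model = build_ms_drcn(model_config, variant)
    return train(model, train_manifest, val_manifest, config, **kwargs)
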