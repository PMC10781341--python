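"""Confusion-matrix metrics, one-vs-rest AUC, noise-robustness sweep, Grad-CAM.

Per-class metrics are computed one-vs-rest from the K x K confusion matrix
(rows = true class, columns = predicted):

    TP_c = cm[c, c];  FP_c = column sum - TP;  FN_c = row sum - TP;
    TN_c = N - TP - FP - FN
    accuracy    = (TP + TN) / N        precision = TP / (TP + FP)
    sensitivity = TP / (TP + FN)       specificity = TN / (TN + FP)
    F1 = 2 * precision * sensitivity / (precision + sensitivity)

Overall accuracy OA = trace(cm) / N; overall precision OP is the macro
average of per-class precision.  When a class receives no predictions the
0/0 precision (and F1) is reported as 0 with a warning.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .architecture import MSDRCN
from .data import DatasetManifest, load_image, preprocess
from .noise import DEFAULT_PSNR_LEVELS, corrupt_image


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= num_classes
                        or y_pred.min() < 0 or y_pred.max() >= num_classes):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def per_class_metrics(cm: np.ndarray) -> dict[str, np.ndarray]:
    cm = np.asarray(cm)
    n = cm.sum()
    if n < 1:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    predicted = tp + fp
    if np.any((predicted == 0) & (tp == 0)):
        warnings.warn("class with no predictions: precision/F1 reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        sensitivity = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        specificity = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        denom = precision + sensitivity
        f1 = np.where(denom > 0, 2 * precision * sensitivity / denom, 0.0)
    return {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
    }


def overall_metrics(cm: np.ndarray) -> tuple[float, float, float]:
    """(overall accuracy, macro precision, macro F1)."""
    cm = np.asarray(cm)
    n = cm.sum()
    if n < 1:
        raise ValueError("empty confusion matrix")
    per = per_class_metrics(cm)
    oa = float(np.trace(cm) / n)
    op = float(per["precision"].mean())
    macro_f1 = float(per["f1"].mean())
    return oa, op, macro_f1


def auc_one_vs_rest(scores: np.ndarray, y_true) -> np.ndarray:
    """Per-class one-vs-rest ROC AUC (midrank ties); NaN for absent classes."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y_true = np.asarray(y_true)
    K = scores.shape[1]
    out = np.full(K, np.nan)
    for c in range(K):
        binary = (y_true == c).astype(int)
        if binary.min() == binary.max():
            continue  # class absent (or only class present): AUC undefined
        out[c] = roc_auc_score(binary, scores[:, c])
    return out


def metric_report(cm: np.ndarray, classes, scores=None, y_true=None) -> dict:
    """Assemble the full metric dictionary (JSON/CSV serializable)."""
    per = per_class_metrics(cm)
    oa, op, macro_f1 = overall_metrics(cm)
    report = {
        "classes": list(classes),
        "confusion_matrix": np.asarray(cm).tolist(),
        "per_class": {
            cls: {k: float(v[i]) for k, v in per.items()}
            for i, cls in enumerate(classes)
        },
        "overall_accuracy": oa,
        "overall_precision": op,
        "macro_f1": macro_f1,
    }
    if scores is not None and y_true is not None:
        auc = auc_one_vs_rest(scores, y_true)
        report["auc"] = {cls: (None if np.isnan(auc[i]) else float(auc[i]))
                         for i, cls in enumerate(classes)}
    return report


def save_report(report: dict, out_dir: str | Path, stem: str = "metrics"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(json.dumps(report, indent=2))
    with open(out_dir / f"{stem}.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "accuracy", "precision", "sensitivity",
                         "specificity", "f1"])
        for cls, vals in report["per_class"].items():
            writer.writerow([cls] + [vals[k] for k in
                                     ("accuracy", "precision", "sensitivity",
                                      "specificity", "f1")])
        writer.writerow(["overall", report["overall_accuracy"],
                         report["overall_precision"], "", "",
                         report["macro_f1"]])


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def predict_images(model: MSDRCN, images, mean: float, std: float,
                   batch_size: int = 32) -> np.ndarray:
    """Logit matrix (N, K) for a list of raw-intensity images."""
    size = model.config.input_size
    model.eval()
    chunks = []
    with nn.no_grad():
        for lo in range(0, len(images), batch_size):
            x = np.stack([preprocess(im, size, mean, std)
                          for im in images[lo:lo + batch_size]])
            chunks.append(model(nn.Tensor(x)).data.copy())
    return np.concatenate(chunks, axis=0)


def evaluate_manifest(model: MSDRCN, manifest: DatasetManifest, mean: float,
                      std: float, batch_size: int = 32) -> dict:
    images = [load_image(p) for p, _ in manifest.records]
    y = manifest.labels_as_indices()
    logits = predict_images(model, images, mean, std, batch_size)
    cm = confusion_matrix(y, logits.argmax(axis=1), len(manifest.classes))
    return metric_report(cm, manifest.classes, scores=logits, y_true=y)


def robustness_sweep(model: MSDRCN, manifest: DatasetManifest, noise_kind: str,
                     psnr_levels=DEFAULT_PSNR_LEVELS, seed: int = 0, *,
                     mean: float, std: float, batch_size: int = 32,
                     images: list | None = None) -> list[tuple[float, float]]:
    """Overall accuracy at each PSNR corruption level; (level, OA) pairs.

    Corruption happens in the stored 8-bit intensity domain before
    preprocessing, with per-image seeds ``seed + index``.  A level of
    ``inf`` evaluates the clean set.
    """
    if images is None:
        images = [load_image(p) for p, _ in manifest.records]
    y = manifest.labels_as_indices()
    K = len(manifest.classes)
    table = []
    for level in psnr_levels:
        noisy = [corrupt_image(im, noise_kind, level, seed=seed + i)
                 for i, im in enumerate(images)]
        logits = predict_images(model, noisy, mean, std, batch_size)
        oa = float((logits.argmax(axis=1) == y).mean())
        table.append((float(level), oa))
    return table


def save_sweep_csv(rows, path: str | Path):
    """rows: iterable of (noise_kind, psnr_db, oa)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["noise_kind", "psnr_db", "oa"])
        writer.writerows(rows)


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and (sample) standard deviation over replicate runs."""
    values = np.asarray(values, dtype=np.float64)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def grad_cam(model: MSDRCN, image: np.ndarray, target_class: int,
             layer: str | None = None, *, mean: float = 0.5,
             std: float = 0.25) -> np.ndarray:
    """Gradient-weighted class activation map, input-sized, in [0, 1].

    ``image`` is a raw-intensity 2-D array; preprocessing matches inference.
    Channel weights are the spatial mean of the target logit's gradient at
    the chosen feature map (default: the finest fused scale when fusion is
    present, else the last backbone stage); the map is the ReLU of the
    weighted activation sum, bilinearly upsampled and min-max normalized.
    An all-zero map (e.g. constant logits) stays all-zero.
    """
    valid = model.feature_names()
    if layer is None:
        layer = "fused1" if model.use_ffb else "stage4"
    if layer not in valid:
        raise ValueError(f"unknown layer {layer!r}; valid layers: {valid}")
    size = model.config.input_size
    x = nn.Tensor(preprocess(image, size, mean, std)[None])
    model.eval()
    logits, feats = model.forward_with_features(x)
    sel = logits[0, int(target_class)]
    model.zero_grad()
    sel.backward()
    fmap = feats[layer]
    if fmap.grad is None:
        cam = np.zeros(fmap.shape[2:])
    else:
        wts = fmap.grad.mean(axis=(2, 3))  # (1, C)
        cam = np.maximum((wts[:, :, None, None] * fmap.data).sum(axis=1), 0.0)[0]
    Mr = nn.resize_matrix(cam.shape[0], size)
    Mc = nn.resize_matrix(cam.shape[1], size)
    cam = Mr @ cam @ Mc.T
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min())
    return np.clip(cam, 0.0, 1.0)


def save_cam_overlay(image: np.ndarray, cam: np.ndarray, path: str | Path,
                     alpha: float = 0.45):
    """Write a jet-colormap heatmap blended over the grayscale image."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import cm as mpl_cm
    from PIL import Image as PILImage
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    Mr = nn.resize_matrix(img.shape[0], cam.shape[0])
    Mc = nn.resize_matrix(img.shape[1], cam.shape[1])
    img = Mr @ img @ Mc.T
    heat = mpl_cm.jet(cam)[..., :3]
    base = np.repeat(img[..., None], 3, axis=2)
    blend = np.clip((1 - alpha) * base + alpha * heat, 0, 1)
    PILImage.fromarray((blend * 255).astype(np.uint8)).save(path)
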