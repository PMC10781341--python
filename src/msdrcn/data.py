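"""Dataset discovery, preprocessing, augmentation, and splitting.

Datasets follow the class-per-directory layout of the public retinal OCT
collections: ``root/<class>/<image>`` with classes CNV, DME, Drusen, Normal.
Images are 8-bit grayscale PNG/JPEG/TIFF.

Preprocessing resizes to a square network input (bilinear, half-pixel
centers) and standardizes with scalar mean/std computed over the training
images in the [0, 1] intensity domain.  Augmentation applies, in order,
random rotation, isotropic scaling, brightness, and horizontal flip — all
ranges per the training protocol (±15°, ±20 %, ±20 %, flip p=0.5).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .architecture import DEFAULT_CLASSES
from .nn import resize_matrix

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass
class DatasetManifest:
    """Ordered (path, label) records with a class vocabulary."""

    records: list[tuple[str, str]]
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self):
        self.classes = tuple(self.classes)
        vocab = set(self.classes)
        for path, label in self.records:
            if label not in vocab:
                raise ValueError(f"label {label!r} not in vocabulary {self.classes}")

    @property
    def counts(self) -> dict[str, int]:
        c = {k: 0 for k in self.classes}
        for _, label in self.records:
            c[label] += 1
        return c

    def labels_as_indices(self) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[label] for _, label in self.records], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.records)

    def save_csv(self, path: str | Path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label"])
            writer.writerows(self.records)

    @classmethod
    def load_csv(cls, path: str | Path,
                 classes: tuple[str, ...] = DEFAULT_CLASSES) -> "DatasetManifest":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)
            records = [(row[0], row[1]) for row in reader]
        return cls(records, classes)


@dataclass
class AugmentationPolicy:
    """Symmetric augmentation ranges; all defaults follow the training recipe."""

    rotation_deg: float = 15.0
    scale_frac: float = 0.20
    brightness_frac: float = 0.20
    hflip: bool = True
    hflip_prob: float = 0.5

    def __post_init__(self):
        if min(self.rotation_deg, self.scale_frac, self.brightness_frac) < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must lie in [0, 1]")


IDENTITY_POLICY = AugmentationPolicy(0.0, 0.0, 0.0, hflip=False)


def scan_dataset(root: str | Path,
                 classes: tuple[str, ...] = DEFAULT_CLASSES) -> DatasetManifest:
    """Recursively list class-per-directory image files, lexicographic order."""
    root = Path(root)
    records: list[tuple[str, str]] = []
    for cls in classes:
        class_dir = root / cls
        if not class_dir.is_dir():
            raise FileNotFoundError(f"missing class directory: {class_dir}")
        files = sorted(p for p in class_dir.rglob("*")
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        skipped = [p for p in class_dir.rglob("*")
                   if p.is_file() and p.suffix.lower() not in IMAGE_EXTENSIONS]
        if skipped:
            warnings.warn(f"skipped {len(skipped)} non-image files under {class_dir}")
        records.extend((str(p), cls) for p in files)
    if not records:
        raise ValueError(f"no images found under {root}")
    return DatasetManifest(records, classes)


def load_image(path: str | Path) -> np.ndarray:
    """Read an image as 2-D float64 grayscale in [0, 255]."""
    try:
        with Image.open(path) as img:
            return np.asarray(img.convert("L"), dtype=np.float64)
    except OSError as exc:
        raise OSError(f"unreadable image {path}: {exc}") from exc


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to size x size via separable interpolation matrices."""
    Mr = resize_matrix(image.shape[0], size)
    Mc = resize_matrix(image.shape[1], size)
    return Mr @ image @ Mc.T


def preprocess(image: np.ndarray, size: int = 224, mean: float = 0.5,
               std: float = 0.25, max_val: float = 255.0) -> np.ndarray:
    """Resize + standardize a raw-intensity image to a (1, size, size) input."""
    if std <= 0:
        raise ValueError("std must be positive")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = image.mean(axis=2)
    resized = resize_image(image, size)
    return ((resized / max_val - mean) / std)[None].astype(np.float32)


def normalization_stats(manifest: DatasetManifest, size: int = 224,
                        max_val: float = 255.0) -> tuple[float, float]:
    """Scalar mean/std of the resized training images in [0, 1]."""
    total, total_sq, n = 0.0, 0.0, 0
    for path, _ in manifest.records:
        img = resize_image(load_image(path), size) / max_val
        total += img.sum()
        total_sq += (img ** 2).sum()
        n += img.size
    mean = total / n
    var = total_sq / n - mean ** 2
    return float(mean), float(np.sqrt(max(var, 1e-12)))


def augment(image: np.ndarray, policy: AugmentationPolicy,
            rng_seed: int = 0) -> np.ndarray:
    """Rotate -> scale -> brightness -> flip, each sampled uniformly.

    Works in the raw intensity domain; rotation/scale use one bilinear
    affine resampling about the image center with edge padding.
    """
    rng = np.random.default_rng(rng_seed)
    image = np.asarray(image, dtype=np.float64)
    angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
    scale = 1.0 + rng.uniform(-policy.scale_frac, policy.scale_frac)
    brightness = 1.0 + rng.uniform(-policy.brightness_frac, policy.brightness_frac)
    flip = policy.hflip and rng.uniform() < policy.hflip_prob
    if angle != 0.0 or scale != 1.0:
        theta = np.deg2rad(angle)
        # output->input map: rotate by -angle and divide by scale
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]]) / scale
        center = (np.array(image.shape) - 1) / 2.0
        offset = center - rot @ center
        image = ndimage.affine_transform(image, rot, offset=offset, order=1,
                                         mode="nearest")
    if brightness != 1.0:
        image = image * brightness
    if flip:
        image = image[:, ::-1]
    return np.ascontiguousarray(image)


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency class weights w_c = N / (K * n_c)."""
    if isinstance(counts, dict):
        counts = list(counts.values())
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    return counts.sum() / (len(counts) * counts)


def stratified_split(manifest: DatasetManifest, val_fraction: float,
                     seed: int = 0) -> tuple[DatasetManifest, DatasetManifest]:
    """Per-class random split into train/validation manifests."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in manifest.classes:
        members = [r for r in manifest.records if r[1] == cls]
        if not members:
            continue
        n_val = int(round(len(members) * val_fraction))
        if n_val == 0 and len(members) >= 2:
            n_val = 1
        if len(members) == 1 and val_fraction >= 0.5:
            warnings.warn(f"class {cls!r} has a single member; kept in train")
            n_val = 0
        order = rng.permutation(len(members))
        val_idx = set(order[:n_val].tolist())
        for i, rec in enumerate(members):
            (val if i in val_idx else train).append(rec)
    return (DatasetManifest(train, manifest.classes),
            DatasetManifest(val, manifest.classes))
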