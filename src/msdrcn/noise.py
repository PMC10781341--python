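"""PSNR computation and PSNR-calibrated image corruption.

The robustness benchmark corrupts stored 8-bit test images with either
additive Gaussian noise or multiplicative speckle noise, calibrated
analytically so the *expected* PSNR against the clean image equals a
requested target:

* Gaussian: ``f = x + n``, ``n ~ N(0, sigma^2)`` with
  ``sigma = max_val * 10^(-PSNR/20)``, so ``E[MSE] = sigma^2``.
* Speckle: ``f = x * m``, ``m ~ N(1, sigma_m^2)`` with
  ``sigma_m = max_val * 10^(-PSNR/20) / rms(x)``, so
  ``E[MSE] = sigma_m^2 * mean(x^2)`` hits the same target.  The additive
  term of the speckle model is negligible next to the multiplicative one
  and is dropped.

No clipping is applied during corruption — clipping would bias the achieved
PSNR above target; values are clipped to [0, max_val] only when exporting to
8-bit files, and achieved PSNR is always logged pre-clip.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterator

import numpy as np
from PIL import Image

DEFAULT_PSNR_LEVELS = (35.0, 32.0, 29.0, 26.0, 23.0, 20.0)


def psnr(reference: np.ndarray, test: np.ndarray, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio 20*log10(max_val / sqrt(MSE)), in dB.

    Returns ``inf`` for identical images (MSE = 0).
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {test.shape}")
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    mse = np.mean((reference - test) ** 2)
    if mse == 0:
        return float("inf")
    return float(20.0 * np.log10(max_val / np.sqrt(mse)))


def _noise_sigma(target_psnr: float, max_val: float) -> float:
    return max_val * 10.0 ** (-target_psnr / 20.0)


def add_gaussian_noise(image: np.ndarray, target_psnr: float,
                       max_val: float = 255.0, seed: int = 0) -> np.ndarray:
    """Additive zero-mean Gaussian noise calibrated to an expected PSNR."""
    image = np.asarray(image, dtype=np.float64)
    if np.isinf(target_psnr):
        return image.copy()
    sigma = _noise_sigma(target_psnr, max_val)
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma, image.shape)


def add_speckle_noise(image: np.ndarray, target_psnr: float,
                      max_val: float = 255.0, seed: int = 0) -> np.ndarray:
    """Multiplicative unit-mean Gaussian speckle calibrated to an expected PSNR."""
    image = np.asarray(image, dtype=np.float64)
    rms = float(np.sqrt(np.mean(image ** 2)))
    if rms == 0:
        raise ValueError("speckle strength undefined for an all-zero image")
    if np.isinf(target_psnr):
        return image.copy()
    sigma_m = _noise_sigma(target_psnr, max_val) / rms
    rng = np.random.default_rng(seed)
    return image * rng.normal(1.0, sigma_m, image.shape)


NOISE_KINDS = {"gaussian": add_gaussian_noise, "speckle": add_speckle_noise}


def corrupt_image(image: np.ndarray, noise_kind: str, target_psnr: float,
                  max_val: float = 255.0, seed: int = 0) -> np.ndarray:
    try:
        fn = NOISE_KINDS[noise_kind]
    except KeyError:
        raise ValueError(
            f"unknown noise kind {noise_kind!r}; choose from {sorted(NOISE_KINDS)}")
    return fn(image, target_psnr, max_val=max_val, seed=seed)


def corrupt_test_set(manifest, noise_kind: str, target_psnr: float,
                     seed: int = 0, max_val: float = 255.0
                     ) -> Iterator[tuple[str, np.ndarray, float]]:
    """Corrupt every manifest image; yields (path, noisy image, achieved dB).

    Per-image seeds derive as ``seed + index`` so a rerun reproduces the
    identical corrupted set.  Corruption happens in the stored 8-bit
    intensity domain, before any resize/normalization.
    """
    if noise_kind not in NOISE_KINDS:
        raise ValueError(
            f"unknown noise kind {noise_kind!r}; choose from {sorted(NOISE_KINDS)}")
    for index, (path, _label) in enumerate(manifest.records):
        clean = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
        noisy = corrupt_image(clean, noise_kind, target_psnr,
                              max_val=max_val, seed=seed + index)
        yield str(path), noisy, psnr(clean, noisy, max_val)


def write_corrupted_tree(manifest, noise_kind: str, target_psnr: float,
                         out_root: str | Path, seed: int = 0,
                         max_val: float = 255.0) -> Path:
    """Export a corrupted copy of the dataset tree plus an achieved-PSNR CSV."""
    out_root = Path(out_root)
    rows = []
    for (path, label), (_, noisy, achieved) in zip(
            manifest.records,
            corrupt_test_set(manifest, noise_kind, target_psnr, seed, max_val)):
        dest = out_root / label / Path(path).name
        dest.parent.mkdir(parents=True, exist_ok=True)
        eight_bit = np.clip(np.round(noisy), 0, max_val).astype(np.uint8)
        Image.fromarray(eight_bit, mode="L").save(dest)
        rows.append((str(dest), target_psnr, achieved))
    log_path = out_root / f"psnr_log_{noise_kind}_{target_psnr:g}db.csv"
    with open(log_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "target_db", "achieved_db"])
        writer.writerows(rows)
    return out_root
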