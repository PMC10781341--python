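"""Synthetic retinal OCT B-scan phantoms.

Every phantom renders a stack of smooth, gently curved reflective bands
(retinal strata) over a dark background, then injects class-specific lesion
morphology:

* **Drusen** — small dome-shaped elevations of the bright outer band,
  mimicking sub-RPE extracellular deposits;
* **DME** — round hypo-reflective intraretinal cysts plus diffuse band
  thickening;
* **CNV** — one larger sub-retinal hypo-reflective fluid pocket adjacent to
  a hyper-reflective fibrotic scar blob;
* **Normal** — no lesion.

Finally multiplicative speckle ``x * m`` with ``m ~ N(1, sigma^2)`` is
applied and intensities clamp to [0, 1].  A binary mask marks lesion pixels
(empty for Normal) to support Grad-CAM localization checks.  Geometry is
deliberately low-dimensional — sinusoidal boundaries, parametric lesions —
so the class signal is carried by lesion morphology, not texture.

Everything is deterministic given the spec seed, at both the single-image
and the dataset level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage, signal

from .architecture import DEFAULT_CLASSES
from .data import DatasetManifest

_BAND_REFLECTIVITY = (0.55, 0.30, 0.48, 0.35, 0.42, 0.85)  # last = RPE, brightest
_BACKGROUND = 0.04
_CYST_INTENSITY = 0.07
_SCAR_INTENSITY = 0.95


def default_lesion_params(class_label: str, height: int, width: int) -> dict:
    """Canonical lesion geometry per class, scaled to the image size."""
    h, w = height, width
    if class_label == "Drusen":
        return {"bump_count": 4, "bump_width": 0.05 * w, "bump_height": 0.07 * h}
    if class_label == "DME":
        return {"cyst_count": 3, "cyst_radius": 0.07 * h, "thickening": 1.3}
    if class_label == "CNV":
        return {"pocket_radius": 0.11 * h, "scar_radius": 0.055 * h}
    return {}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic B-scan."""

    class_label: str = "Normal"
    height: int = 224
    width: int = 224
    layer_count: int = 6
    curvature: float = 1.0
    speckle_sigma: float = 0.3
    seed: int = 0
    lesion_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.class_label not in DEFAULT_CLASSES:
            raise ValueError(f"class_label must be one of {DEFAULT_CLASSES}")
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom smaller than 16 px is not renderable")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be non-negative")
        if not self.lesion_params:
            self.lesion_params = default_lesion_params(
                self.class_label, self.height, self.width)
        if self.class_label == "Normal" and self.lesion_params:
            raise ValueError("Normal phantoms take no lesion parameters")
        for key, value in self.lesion_params.items():
            if "radius" in key and value * 2 > min(self.height, self.width):
                raise ValueError(f"lesion {key}={value} larger than the image")


def _band_boundaries(spec: PhantomSpec, rng: np.random.Generator,
                     thickening: float = 1.0) -> np.ndarray:
    """(layer_count+1, W) row coordinates of band boundaries per column."""
    H, W = spec.height, spec.width
    x = np.arange(W) / W
    phase = rng.uniform(0, 2 * np.pi)
    freq = rng.uniform(0.7, 1.4)
    top = H * (0.28 + 0.05 * spec.curvature * np.sin(2 * np.pi * freq * x + phase)
               + 0.02 * spec.curvature * np.sin(4 * np.pi * freq * x + 2 * phase))
    thickness = H * 0.34 * thickening
    # fixed band proportions with mild per-phantom jitter
    props = np.array([0.18, 0.16, 0.20, 0.16, 0.14, 0.16][: spec.layer_count])
    props = props * rng.uniform(0.9, 1.1, size=props.size)
    props = props / props.sum()
    bounds = np.empty((spec.layer_count + 1, W))
    bounds[0] = top
    for i, p in enumerate(props):
        bounds[i + 1] = bounds[i] + p * thickness
    return bounds


def _render_bands(bounds: np.ndarray, H: int, W: int) -> np.ndarray:
    yy = np.arange(H)[:, None]
    img = np.full((H, W), _BACKGROUND)
    refl = list(_BAND_REFLECTIVITY)
    n_bands = bounds.shape[0] - 1
    for b in range(n_bands):
        inside = (yy >= bounds[b]) & (yy < bounds[b + 1])
        img[inside] = refl[b % len(refl)] if b < n_bands - 1 else refl[-1]
    return img


def _ellipse_mask(H: int, W: int, cy: float, cx: float,
                  ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[:H, :W]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_bscan(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns (image in [0,1], binary lesion mask)."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    params = spec.lesion_params
    thickening = params.get("thickening", 1.0)
    bounds = _band_boundaries(spec, rng, thickening)
    mask = np.zeros((H, W), dtype=bool)

    if spec.class_label == "Drusen":
        # dome elevations of the bright outer band: lift its top edge locally
        xs = np.arange(W)
        rpe_top = bounds[-2].copy()
        elev = np.zeros(W)
        centers = rng.uniform(0.1 * W, 0.9 * W, size=int(params["bump_count"]))
        for xc in centers:
            elev += params["bump_height"] * np.exp(
                -((xs - xc) / params["bump_width"]) ** 2)
        bounds[-2] = rpe_top - elev
        img = _render_bands(bounds, H, W)
        yy = np.arange(H)[:, None]
        mask = (yy >= bounds[-2]) & (yy < rpe_top)
    elif spec.class_label == "DME":
        img = _render_bands(bounds, H, W)
        for _ in range(int(params["cyst_count"])):
            r = params["cyst_radius"] * rng.uniform(0.7, 1.2)
            cy = rng.uniform(bounds[1].mean() + r, bounds[-2].mean() - r)
            cx = rng.uniform(0.15 * W, 0.85 * W)
            cyst = _ellipse_mask(H, W, cy, cx, r, r * rng.uniform(1.0, 1.5))
            img[cyst] = _CYST_INTENSITY
            mask |= cyst
    elif spec.class_label == "CNV":
        img = _render_bands(bounds, H, W)
        rp = params["pocket_radius"]
        # keep the fluid pocket enclosed by retinal tissue so it reads as a
        # hypo-reflective cavity, not a notch open to the background
        lo = bounds[1].mean() + 0.8 * rp
        hi = bounds[-2].mean() - 0.3 * rp
        cy = rng.uniform(lo, hi) if hi > lo else 0.5 * (bounds[0].mean()
                                                        + bounds[-1].mean())
        cx = rng.uniform(0.3 * W, 0.7 * W)
        pocket = _ellipse_mask(H, W, cy, cx, rp, rp * 1.6)
        img[pocket] = _CYST_INTENSITY
        rs = params["scar_radius"]
        scar = _ellipse_mask(H, W, min(bounds[-1].mean() + 0.8 * rs, H - rs),
                             cx + rng.uniform(-0.15, 0.15) * W, rs, rs * 1.3)
        img[scar] = _SCAR_INTENSITY
        mask = pocket | scar
    else:
        img = _render_bands(bounds, H, W)

    if spec.speckle_sigma > 0:
        img = img * rng.normal(1.0, spec.speckle_sigma, img.shape)
    return np.clip(img, 0.0, 1.0), mask.astype(np.uint8)


def generate_dataset(n_per_class: int, root: str | Path, global_seed: int = 0,
                     speckle_sigma: float = 0.3, height: int = 224,
                     width: int = 224,
                     classes: tuple[str, ...] = DEFAULT_CLASSES
                     ) -> DatasetManifest:
    """Write a class-per-directory phantom tree with parallel lesion masks.

    Per-image seed = ``global_seed + running index``, so reruns reproduce
    byte-identical files.  Returns the manifest (also saved as CSV).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    root = Path(root)
    mask_root = root.parent / (root.name + "_masks")
    records = []
    index = 0
    for cls in classes:
        (root / cls).mkdir(parents=True, exist_ok=True)
        (mask_root / cls).mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            spec = PhantomSpec(class_label=cls, height=height, width=width,
                               speckle_sigma=speckle_sigma,
                               seed=global_seed + index)
            img, mask = generate_bscan(spec)
            name = f"{cls.lower()}_{i:04d}.png"
            Image.fromarray(np.round(img * 255).astype(np.uint8), "L").save(
                root / cls / name)
            Image.fromarray(mask * 255, "L").save(mask_root / cls / name)
            records.append((str(root / cls / name), cls))
            index += 1
    manifest = DatasetManifest(records, classes)
    manifest.save_csv(root / "manifest.csv")
    return manifest


def mask_path_for(image_path: str | Path) -> Path:
    """Locate the lesion mask written alongside a generated phantom."""
    p = Path(image_path)
    return p.parent.parent.parent / (p.parent.parent.name + "_masks") / p.parent.name / p.name


def baseline_features(image: np.ndarray) -> np.ndarray:
    """Five hand-crafted features separating the phantom classes.

    (mean band thickness, dark-blob count, bright-blob area fraction,
    outer-band bump count, intensity variance).  Used as an independent
    learnability check of the generator — a shallow classifier on these
    features should separate the classes well above chance.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:  # 8-bit input
        img = img / 255.0
    H, W = img.shape
    smooth = ndimage.uniform_filter(img, size=max(2, H // 56))
    tissue = smooth > 0.15
    thickness = tissue.sum(axis=0).mean() / H
    # dark blobs: hypo-reflective holes inside the tissue envelope
    envelope = ndimage.binary_fill_holes(tissue)
    dark = envelope & (smooth < 0.12)
    labels, n_dark = ndimage.label(dark)
    sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n_dark + 1))
    min_area = (H * W) / 2000
    dark_count = float((sizes > min_area).sum())
    bright_area = float((smooth > 0.70).mean())
    # bump count: peaks of the top profile of the bright outer band
    bright = smooth > 0.70
    has_bright = bright.any(axis=0)
    if has_bright.sum() < 3:
        n_peaks = 0.0
    else:
        top = bright.argmax(axis=0).astype(np.float64)
        fill = np.median(top[has_bright])
        prof = np.where(has_bright, top, fill)
        prof = ndimage.uniform_filter1d(prof, size=3)
        baseline = ndimage.uniform_filter1d(prof, size=max(3, W // 4))
        peaks, _ = signal.find_peaks(baseline - prof, height=0.035 * H,
                                     distance=max(2, W // 25))
        n_peaks = float(len(peaks))
    return np.array([thickness, dark_count, bright_area, n_peaks, img.var()])
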