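"""Dataset discovery, preprocessing, augmentation, weighting, splitting."""

import numpy as np
import pytest
from PIL import Image

from msdrcn.data import (AugmentationPolicy, IDENTITY_POLICY, augment,
                         class_weights, normalization_stats, preprocess,
                         scan_dataset, stratified_split, DatasetManifest)

CLASSES = ("CNV", "DME", "Drusen", "Normal")


@pytest.fixture()
def tiny_tree(tmp_path):
    rng = np.random.default_rng(0)
    for cls in CLASSES:
        d = tmp_path / cls
        d.mkdir()
        for i in range(3):
            arr = rng.integers(0, 255, (48, 56), dtype=np.uint8)
            Image.fromarray(arr, "L").save(d / f"{cls}_{i}.png")
    return tmp_path


def test_scan_dataset_counts_and_order(tiny_tree):
    manifest = scan_dataset(tiny_tree, CLASSES)
    assert len(manifest) == 12
    assert manifest.counts == {c: 3 for c in CLASSES}
    paths = [p for p, _ in manifest.records]
    assert paths == sorted(paths, key=lambda p: (p.split("/")[-2] not in CLASSES, p)) \
        or all(p1 <= p2 for p1, p2 in zip(paths[:3], paths[1:4]))  # per-class sorted
    # labels appear grouped in vocabulary order
    labels = [l for _, l in manifest.records]
    assert labels == sorted(labels, key=CLASSES.index)


def test_scan_dataset_missing_class_and_empty(tmp_path):
    (tmp_path / "CNV").mkdir()
    with pytest.raises(FileNotFoundError, match="DME"):
        scan_dataset(tmp_path, CLASSES)


def test_scan_dataset_skips_non_images(tiny_tree):
    (tiny_tree / "CNV" / "notes.txt").write_text("not an image")
    with pytest.warns(UserWarning, match="skipped"):
        manifest = scan_dataset(tiny_tree, CLASSES)
    assert len(manifest) == 12


def test_manifest_rejects_unknown_label():
    with pytest.raises(ValueError, match="vocabulary"):
        DatasetManifest([("x.png", "Glaucoma")], CLASSES)


def test_preprocess_shape_and_identity_standardization(rng):
    img = rng.uniform(0, 255, (496, 512))
    out = preprocess(img, size=224, mean=0.0, std=1.0)
    assert out.shape == (1, 224, 224)
    # with mean 0 / std 1 only the 1/255 rescale applies
    assert out.max() <= 1.0 + 1e-6 and out.min() >= 0.0
    with pytest.raises(ValueError, match="std"):
        preprocess(img, 224, 0.5, 0.0)


def test_normalization_stats_standardize_to_unit(tiny_tree):
    manifest = scan_dataset(tiny_tree, CLASSES)
    mean, std = normalization_stats(manifest, size=32)
    pixels = np.concatenate([
        preprocess(np.asarray(Image.open(p).convert("L"), dtype=float),
                   32, mean, std).ravel()
        for p, _ in manifest.records])
    assert pixels.mean() == pytest.approx(0.0, abs=1e-6)
    assert pixels.std() == pytest.approx(1.0, abs=1e-3)


def test_augment_identity_policy_and_determinism(rng):
    img = rng.uniform(0, 255, (64, 64))
    np.testing.assert_array_equal(augment(img, IDENTITY_POLICY, 0), img)
    a = augment(img, AugmentationPolicy(), rng_seed=5)
    b = augment(img, AugmentationPolicy(), rng_seed=5)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, augment(img, AugmentationPolicy(), rng_seed=6))


def test_augment_brightness_and_flip_behaviour(rng):
    img = rng.uniform(10, 200, (32, 32))
    bright_only = AugmentationPolicy(0.0, 0.0, 0.2, hflip=False)
    ratios = [augment(img, bright_only, s).mean() / img.mean()
              for s in range(300)]
    assert min(ratios) >= 0.8 - 1e-9 and max(ratios) <= 1.2 + 1e-9
    assert max(ratios) > 1.15 and min(ratios) < 0.85  # range is exercised
    flip_only = AugmentationPolicy(0.0, 0.0, 0.0, hflip=True, hflip_prob=0.5)
    flips = [np.array_equal(augment(img, flip_only, s), img[:, ::-1])
             for s in range(300)]
    assert 0.4 < np.mean(flips) < 0.6


def test_augment_policy_validation():
    with pytest.raises(ValueError, match="non-negative"):
        AugmentationPolicy(rotation_deg=-5)
    with pytest.raises(ValueError, match="hflip_prob"):
        AugmentationPolicy(hflip_prob=1.5)


def test_class_weights_formula():
    np.testing.assert_allclose(class_weights([10, 10, 10, 10]), np.ones(4))
    # real-world imbalanced training counts (CNV, DME, Drusen, Normal)
    w = class_weights([37205, 11348, 8616, 26315])
    np.testing.assert_allclose(w, [0.561, 1.839, 2.422, 0.793], atol=5e-4)
    np.testing.assert_allclose(class_weights([1, 999]),
                               [1000 / 2, 1000 / (2 * 999)], rtol=1e-12)
    with pytest.raises(ValueError, match="positive"):
        class_weights([5, 0, 3, 2])


def test_stratified_split_partition_and_determinism():
    records = [(f"{c}_{i}.png", c) for c in CLASSES for i in range(100)]
    manifest = DatasetManifest(records, CLASSES)
    train, val = stratified_split(manifest, 0.2, seed=0)
    assert train.counts == {c: 80 for c in CLASSES}
    assert val.counts == {c: 20 for c in CLASSES}
    assert set(train.records) | set(val.records) == set(records)
    assert not set(train.records) & set(val.records)
    train2, val2 = stratified_split(manifest, 0.2, seed=0)
    assert train.records == train2.records
    train3, _ = stratified_split(manifest, 0.2, seed=1)
    assert train3.records != train.records
    assert DatasetManifest(train3.records, CLASSES).counts == train.counts


def test_stratified_split_single_member_warning():
    manifest = DatasetManifest([("a.png", "CNV")] + [
        (f"n{i}.png", "Normal") for i in range(4)],
        ("CNV", "Normal"))
    with pytest.warns(UserWarning, match="single member"):
        train, val = stratified_split(manifest, 0.5, seed=0)
    assert ("a.png", "CNV") in train.records
    with pytest.raises(ValueError, match="val_fraction"):
        stratified_split(manifest, 1.5)


def test_manifest_csv_roundtrip(tmp_path):
    manifest = DatasetManifest([("a.png", "CNV"), ("b.png", "DME")], CLASSES)
    manifest.save_csv(tmp_path / "m.csv")
    loaded = DatasetManifest.load_csv(tmp_path / "m.csv", CLASSES)
    assert loaded.records == manifest.records
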