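"""Block-level checks: closed forms, threshold bounds, residual identities,
shape contracts, parameter counting, and agreement with independent
straight-line reference implementations in evaluation mode."""

import numpy as np
import pytest

from msdrcn import nn
from msdrcn.architecture import (GuideAttention, ModelConfig, MSDRCN,
                                 MultiScaleContextBlock, SoftDenoiseBlock,
                                 FeatureFusionBlock, build_ms_drcn,
                                 count_parameters, desk_config,
                                 load_checkpoint, save_checkpoint, VARIANTS)

from _reference import (ref_ga_forward, ref_mcb_forward, ref_sdb_forward,
                        ref_sdb_threshold, ref_soft_threshold)


def _warmup_eval(block, *shapes, seed=7, passes=3):
    """Populate running BN statistics with a few training passes, then eval."""
    rng = np.random.default_rng(seed)
    block.train()
    for _ in range(passes):
        args = [nn.Tensor(rng.normal(size=s).astype(np.float64)) for s in shapes]
        with nn.no_grad():
            block(*args)
    block.eval()


# ---------------------------------------------------------------------------
# soft thresholding
# ---------------------------------------------------------------------------

def test_soft_threshold_piecewise_branches():
    out = nn.soft_threshold(nn.Tensor(np.array([5.0, -5.0, 1.0, 0.0])),
                            nn.Tensor(np.array(2.0)))
    np.testing.assert_array_equal(out.data, [3.0, -3.0, 0.0, 0.0])


def test_soft_threshold_zero_tau_is_identity(rng):
    x = rng.normal(size=(3, 4, 5))
    out = nn.soft_threshold(nn.Tensor(x), nn.Tensor(np.array(0.0)))
    np.testing.assert_array_equal(out.data, x)


def test_soft_threshold_odd_nonexpansive_continuous(rng):
    x = rng.normal(size=2000) * 3
    tau = rng.uniform(0, 2, size=2000)
    y = nn.soft_threshold(nn.Tensor(x), nn.Tensor(tau)).data
    y_neg = nn.soft_threshold(nn.Tensor(-x), nn.Tensor(tau)).data
    np.testing.assert_allclose(y_neg, -y, atol=1e-15)           # odd
    assert np.all(np.abs(y) <= np.abs(x) + 1e-15)               # non-expansive
    np.testing.assert_allclose(np.abs(y), np.maximum(np.abs(x) - tau, 0),
                               atol=1e-15)                      # magnitude law
    assert np.all((np.sign(y) == np.sign(x)) | (y == 0))        # sign kept


# ---------------------------------------------------------------------------
# SDB
# ---------------------------------------------------------------------------

def test_sdb_threshold_zero_input_gives_zero():
    block = SoftDenoiseBlock(32, 16, rng=np.random.default_rng(0))
    block.eval()
    tau = block.threshold(nn.Tensor(np.zeros((2, 32, 6, 6))))
    np.testing.assert_array_equal(tau.data, 0.0)


def test_sdb_threshold_half_mean_when_logits_zero():
    """With FC2 forced to emit z = 0, sigmoid(0) = 1/2 halves mean |x|."""
    block = SoftDenoiseBlock(16, 16, rng=np.random.default_rng(0))
    block.fc2.weight.data[...] = 0.0
    block.fc2.bias.data[...] = 0.0
    block.eval()
    x = np.random.default_rng(1).normal(size=(3, 16, 5, 5))
    tau = block.threshold(nn.Tensor(x)).data
    np.testing.assert_allclose(tau, 0.5 * np.abs(x).mean(axis=(2, 3)),
                               rtol=1e-12)


def test_sdb_threshold_strictly_below_mean_abs(rng):
    """0 <= tau < mean|x| per (sample, channel) for arbitrary FC weights."""
    for trial in range(20):
        block = SoftDenoiseBlock(32, 16, rng=np.random.default_rng(trial))
        for p in block.parameters():
            # random reinit at a scale where sigmoid stays numerically < 1
            p.data = p.data + rng.normal(size=p.data.shape, scale=0.5)
        _warmup_eval(block, (4, 32, 6, 6), seed=trial)
        x = rng.normal(size=(4, 32, 6, 6))
        tau = block.threshold(nn.Tensor(x)).data
        bound = np.abs(x).mean(axis=(2, 3))
        assert np.all(tau >= 0)
        assert np.all(tau < bound)


def test_sdb_matches_reference(rng):
    block = SoftDenoiseBlock(32, 16, rng=np.random.default_rng(3))
    _warmup_eval(block, (4, 32, 6, 6))
    x = rng.normal(size=(4, 32, 6, 6))
    tau = block.threshold(nn.Tensor(x)).data
    np.testing.assert_allclose(tau, ref_sdb_threshold(x, block), rtol=1e-9)
    y = block(nn.Tensor(x)).data
    np.testing.assert_allclose(y, ref_sdb_forward(x, block), rtol=1e-9)


def test_sdb_zero_input_passthrough_and_channel_mismatch():
    block = SoftDenoiseBlock(16, 16, rng=np.random.default_rng(0))
    block.eval()
    np.testing.assert_array_equal(
        block(nn.Tensor(np.zeros((2, 16, 4, 4)))).data, 0.0)
    with pytest.raises(ValueError, match="channels"):
        block(nn.Tensor(np.zeros((2, 8, 4, 4))))


def test_sdb_forward_piecewise_consequence(rng):
    """Where x > tau: y = 2x - tau; inside the band: y = x."""
    block = SoftDenoiseBlock(8, 4, rng=np.random.default_rng(5))
    _warmup_eval(block, (2, 8, 4, 4))
    x = rng.normal(size=(2, 8, 4, 4)) * 2
    tau = block.threshold(nn.Tensor(x)).data[:, :, None, None]
    y = block(nn.Tensor(x)).data
    np.testing.assert_allclose(np.where(x > tau, 2 * x - tau,
                               np.where(x < -tau, 2 * x + tau, x)), y,
                               rtol=1e-9)


# ---------------------------------------------------------------------------
# MCB
# ---------------------------------------------------------------------------

def test_mcb_preserves_shape_and_matches_reference(rng):
    block = MultiScaleContextBlock(32, 8, 4, (1, 2, 3, 4),
                                   rng=np.random.default_rng(2))
    _warmup_eval(block, (2, 32, 9, 9))
    x = rng.normal(size=(2, 32, 9, 9))
    y = block(nn.Tensor(x)).data
    assert y.shape == x.shape
    np.testing.assert_allclose(y, ref_mcb_forward(x, block), rtol=1e-7,
                               atol=1e-9)


def test_mcb_zero_weights_reduce_to_identity(rng):
    block = MultiScaleContextBlock(32, 8, 4, rng=np.random.default_rng(0))
    block.expand.conv.weight.data[...] = 0.0
    block.eval()
    x = rng.normal(size=(2, 32, 7, 7))
    np.testing.assert_allclose(block(nn.Tensor(x)).data, x, atol=1e-12)


def test_mcb_rejects_indivisible_channels():
    with pytest.raises(ValueError, match="divisible"):
        MultiScaleContextBlock(48, 8, 4)


def test_dilated_conv_receptive_field():
    """A dilation-4 3x3 kernel spans 9 pixels per axis: an impulse response
    confined to offsets {-4, 0, +4}."""
    w = nn.Parameter(np.ones((1, 1, 3, 3)))
    impulse = np.zeros((1, 1, 17, 17))
    impulse[0, 0, 8, 8] = 1.0
    out = nn.conv2d(nn.Tensor(impulse), w, stride=1, padding=4, dilation=4).data
    nz = np.argwhere(out[0, 0] != 0)
    assert nz.min() == 4 and nz.max() == 12  # 9x9 footprint
    assert set(np.unique(nz - 8)) <= {-4, 0, 4}


# ---------------------------------------------------------------------------
# GA / FFB
# ---------------------------------------------------------------------------

def test_ga_shape_contract_and_reference(rng):
    block = GuideAttention(16, rng=np.random.default_rng(4))
    _warmup_eval(block, (2, 16, 12, 12), (2, 16, 6, 6))
    xf = rng.normal(size=(2, 16, 12, 12))
    xc = rng.normal(size=(2, 16, 6, 6))
    y = block(nn.Tensor(xf), nn.Tensor(xc)).data
    assert y.shape == xf.shape
    np.testing.assert_allclose(y, ref_ga_forward(xf, xc, block), rtol=1e-7,
                               atol=1e-9)


def test_ga_zero_refine_is_identity(rng):
    block = GuideAttention(8, rng=np.random.default_rng(0))
    block.refine.conv.weight.data[...] = 0.0
    block.eval()
    xf = rng.normal(size=(1, 8, 8, 8))
    xc = rng.normal(size=(1, 8, 4, 4))
    np.testing.assert_allclose(block(nn.Tensor(xf), nn.Tensor(xc)).data, xf,
                               atol=1e-12)


def test_ga_errors():
    block = GuideAttention(8)
    with pytest.raises(ValueError, match="channel"):
        block(nn.Tensor(np.zeros((1, 8, 8, 8))), nn.Tensor(np.zeros((1, 4, 4, 4))))
    with pytest.raises(ValueError, match="integer"):
        block(nn.Tensor(np.zeros((1, 8, 9, 9))), nn.Tensor(np.zeros((1, 8, 4, 4))))


def test_ffb_shapes_projection_and_bottom_branch(rng):
    channels = (16, 32, 64, 128)
    ffb = FeatureFusionBlock(channels, 16, rng=np.random.default_rng(1))
    ffb.eval()
    feats = [nn.Tensor(rng.normal(size=(2, c, s, s)))
             for c, s in zip(channels, (32, 16, 8, 4))]
    outs = ffb(feats)
    assert [o.shape for o in outs] == [(2, 16, 32, 32), (2, 16, 16, 16),
                                       (2, 16, 8, 8), (2, 16, 4, 4)]
    # coarsest path is exactly the 1x1 projection of its input
    np.testing.assert_array_equal(outs[3].data, ffb.project[3](feats[3]).data)
    # zeroing the GA refinement convs reduces every path to its projection
    for ga in ffb.ga:
        ga.refine.conv.weight.data[...] = 0.0
    outs2 = ffb(feats)
    for o, f, proj in zip(outs2, feats, ffb.project):
        np.testing.assert_allclose(o.data, proj(f).data, atol=1e-10)


def test_ffb_rejects_bad_pyramids(rng):
    ffb = FeatureFusionBlock((8, 16, 32, 64), 16)
    with pytest.raises(ValueError, match="4 scales"):
        ffb([nn.Tensor(np.zeros((1, 8, 8, 8)))] * 3)
    feats = [nn.Tensor(np.zeros((1, c, s, s)))
             for c, s in zip((8, 16, 32, 64), (32, 16, 8, 5))]
    with pytest.raises(ValueError, match="halve"):
        ffb(feats)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def test_model_forward_shapes_and_determinism(rng):
    model = build_ms_drcn(desk_config(seed=0), "ms-drcn").eval()
    x = nn.Tensor(rng.normal(size=(2, 1, 64, 64)).astype(np.float32))
    with nn.no_grad():
        a = model(x).data
        b = model(x).data
    assert a.shape == (2, 4)
    assert np.isfinite(a).all()
    np.testing.assert_array_equal(a, b)  # eval forward is bitwise repeatable


def test_model_three_classes(rng):
    model = build_ms_drcn(desk_config(num_classes=3, seed=1), "ms-drcn").eval()
    with nn.no_grad():
        out = model(nn.Tensor(rng.normal(size=(2, 1, 64, 64)).astype(np.float32)))
    assert out.shape == (2, 3)


def test_model_rejects_bad_input_size(rng):
    model = build_ms_drcn(desk_config(seed=0), "resnet")
    with pytest.raises(ValueError, match="divisible by 32"):
        model(nn.Tensor(np.zeros((1, 1, 60, 60), dtype=np.float32)))


def test_invalid_variant_and_config():
    with pytest.raises(ValueError, match="variant"):
        build_ms_drcn(desk_config(), "resnet+sdb")
    with pytest.raises(ValueError, match="increasing"):
        ModelConfig(stage_channels=(256, 256, 1024, 2048))
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(fusion_channels=100)
    with pytest.raises(ValueError, match="mcb_dilations"):
        ModelConfig(mcb_dilations=(1, 2, 3))


def test_count_parameters_closed_forms():
    conv = nn.Conv2d(1, 8, 3, bias=True)
    assert count_parameters(conv) == 3 * 3 * 1 * 8 + 8
    fc = nn.Linear(10, 4)
    assert count_parameters(fc) == 10 * 4 + 4
    assert count_parameters(nn.Sequential()) == 0


def test_gradient_flow_all_variants(rng):
    """One SGD step on a synthetic batch leaves no block without gradient."""
    cfg = ModelConfig(stage_channels=(32, 64, 128, 256), fusion_channels=32,
                      input_size=32, blocks_per_stage=(1, 1, 1, 1), seed=0)
    x = rng.normal(size=(4, 1, 32, 32)).astype(np.float32)
    labels = np.array([0, 1, 2, 3])
    for variant in VARIANTS:
        model = build_ms_drcn(cfg, variant).train()
        loss = nn.cross_entropy(model(nn.Tensor(x)), labels)
        loss.backward()
        missing = [n for n, p in model.named_parameters() if p.grad is None
                   or not np.any(p.grad)]
        # BN betas of dead-ReLU branches may legitimately see zero grads;
        # demand that >95% of parameter arrays receive signal
        total = sum(1 for _ in model.parameters())
        assert len(missing) / total < 0.05, (variant, missing[:5])


def test_checkpoint_roundtrip(tmp_path, rng):
    model = build_ms_drcn(desk_config(seed=2), "ms-drcn").eval()
    x = nn.Tensor(rng.normal(size=(1, 1, 64, 64)).astype(np.float32))
    with nn.no_grad():
        before = model(x).data.copy()
    path = save_checkpoint(model, tmp_path / "ckpt.npz",
                           extra={"norm_mean": 0.2, "norm_std": 0.1})
    restored, classes = load_checkpoint(path)
    restored.eval()
    with nn.no_grad():
        after = restored(x).data
    np.testing.assert_array_equal(before, after)
    assert classes == ["CNV", "DME", "Drusen", "Normal"]
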