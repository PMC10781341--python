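"""Independent straight-line reference implementations used as test oracles.

Everything here is deliberately naive — explicit Python loops and direct
formula transcription on NumPy arrays — and shares no code with the
package's autodiff engine, so agreement is evidence of correctness rather
than self-consistency.  Only usable at tiny sizes and in evaluation mode
(batch statistics frozen).
"""

import numpy as np


def ref_soft_threshold(x, tau):
    x = np.asarray(x, dtype=np.float64)
    tau = np.broadcast_to(np.asarray(tau, dtype=np.float64), x.shape)
    out = np.empty_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for v in it:
        i = it.multi_index
        t = tau[i]
        if v > t:
            out[i] = v - t
        elif v < -t:
            out[i] = v + t
        else:
            out[i] = 0.0
    return out


def ref_bn_eval(x, gamma, beta, running_mean, running_var, eps=1e-5):
    """Per-channel affine batch norm in evaluation mode; x is (B, C, ...)."""
    shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
    scale = gamma / np.sqrt(running_var + eps)
    return scale.reshape(shape) * (x - running_mean.reshape(shape)) \
        + beta.reshape(shape)


def ref_conv2d(x, w, b=None, stride=1, padding=1, dilation=1):
    """Quadruple-loop 2-D cross-correlation."""
    B, C, H, W = x.shape
    Cout, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out_h = (H + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    out_w = (W + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    out = np.zeros((B, Cout, out_h, out_w))
    for n in range(B):
        for o in range(Cout):
            for i in range(out_h):
                for j in range(out_w):
                    acc = 0.0
                    for ki in range(kh):
                        for kj in range(kw):
                            acc += (w[o, :, ki, kj] *
                                    xp[n, :, i * stride + ki * dilation,
                                       j * stride + kj * dilation]).sum()
                    out[n, o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def ref_bconv_eval(x, block, stride=1):
    """Conv -> eval-mode BN -> ReLU using a package BConv's parameters."""
    conv = block.conv
    y = ref_conv2d(x, conv.weight.data.astype(np.float64), None,
                   stride=stride, padding=conv.padding, dilation=conv.dilation)
    y = ref_bn_eval(y, block.bn.gamma.data.astype(np.float64),
                    block.bn.beta.data.astype(np.float64),
                    block.bn.running_mean, block.bn.running_var,
                    block.bn.eps)
    return np.maximum(y, 0.0)


def ref_bilinear_upsample(x, out_h, out_w):
    """Half-pixel-center bilinear resize with edge clamping, per pixel."""
    B, C, H, W = x.shape
    out = np.zeros((B, C, out_h, out_w))
    for i in range(out_h):
        sy = min(max((i + 0.5) * H / out_h - 0.5, 0.0), H - 1.0)
        y0 = int(np.floor(sy))
        y1 = min(y0 + 1, H - 1)
        fy = sy - y0
        for j in range(out_w):
            sx = min(max((j + 0.5) * W / out_w - 0.5, 0.0), W - 1.0)
            x0 = int(np.floor(sx))
            x1 = min(x0 + 1, W - 1)
            fx = sx - x0
            out[:, :, i, j] = ((1 - fy) * (1 - fx) * x[:, :, y0, x0]
                               + (1 - fy) * fx * x[:, :, y0, x1]
                               + fy * (1 - fx) * x[:, :, y1, x0]
                               + fy * fx * x[:, :, y1, x1])
    return out


def ref_sdb_threshold(x, block):
    """GAP(|x|) -> FC1 -> eval BN -> ReLU -> FC2 -> sigmoid -> scale * GAP."""
    a = np.abs(x).mean(axis=(2, 3))  # (B, C)
    z = a @ block.fc1.weight.data.astype(np.float64).T \
        + block.fc1.bias.data.astype(np.float64)
    z = ref_bn_eval(z[:, :, None, None], block.bn.gamma.data.astype(np.float64),
                    block.bn.beta.data.astype(np.float64),
                    block.bn.running_mean, block.bn.running_var,
                    block.bn.eps)[:, :, 0, 0]
    z = np.maximum(z, 0.0)
    z = z @ block.fc2.weight.data.astype(np.float64).T \
        + block.fc2.bias.data.astype(np.float64)
    return (1.0 / (1.0 + np.exp(-z))) * a


def ref_sdb_forward(x, block):
    tau = ref_sdb_threshold(x, block)
    return ref_soft_threshold(x, tau[:, :, None, None]) + x


def ref_mcb_forward(x, block):
    r = ref_bconv_eval(x, block.reduce)
    gw = block.group_width
    groups = [ref_bconv_eval(r[:, i * gw:(i + 1) * gw], br)
              for i, br in enumerate(block.branches)]
    merged = np.concatenate(groups, axis=1)
    return x + ref_bconv_eval(merged, block.expand)


def ref_ga_forward(x_fine, x_coarse, block):
    up = ref_bilinear_upsample(x_coarse, x_fine.shape[2], x_fine.shape[3])
    f = ref_bn_eval(x_fine, block.bn_fine.gamma.data.astype(np.float64),
                    block.bn_fine.beta.data.astype(np.float64),
                    block.bn_fine.running_mean, block.bn_fine.running_var,
                    block.bn_fine.eps) \
        * ref_bn_eval(up, block.bn_coarse.gamma.data.astype(np.float64),
                      block.bn_coarse.beta.data.astype(np.float64),
                      block.bn_coarse.running_mean, block.bn_coarse.running_var,
                      block.bn_coarse.eps)
    return ref_bconv_eval(f, block.refine) + x_fine


def ref_confusion_and_metrics(y_true, y_pred, K):
    """Loop-and-count confusion matrix and one-vs-rest metric tallies."""
    cm = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    n = len(y_true)
    per = {"accuracy": [], "precision": [], "sensitivity": [],
           "specificity": [], "f1": []}
    for c in range(K):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = n - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        per["accuracy"].append((tp + tn) / n)
        per["precision"].append(prec)
        per["sensitivity"].append(sens)
        per["specificity"].append(spec)
        per["f1"].append(f1)
    oa = sum(cm[c, c] for c in range(K)) / n
    op = float(np.mean(per["precision"]))
    macro_f1 = float(np.mean(per["f1"]))
    return cm, {k: np.array(v) for k, v in per.items()}, (oa, op, macro_f1)


def ref_auc(scores, binary_labels):
    """Pair-counting AUC with half credit for ties (midrank equivalent)."""
    pos = [s for s, b in zip(scores, binary_labels) if b == 1]
    neg = [s for s, b in zip(scores, binary_labels) if b == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
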