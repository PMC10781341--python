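"""Layer modules over the autodiff core: Conv2d, BatchNorm, Linear, BConv.

``Module`` follows the familiar container pattern — submodules and
parameters are discovered by attribute, ``train()``/``eval()`` toggle batch
normalization behaviour, and ``named_parameters()`` yields dotted names used
for checkpoint serialization.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as F
from .tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- discovery --------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}")

    # -- mode -------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- state ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({f"__buf__{n}": b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("__buf__"):
                name = key[len("__buf__"):]
                if bufs[name].shape != value.shape:
                    raise ValueError(f"buffer shape mismatch for {name}")
                bufs[name][...] = value
            else:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"parameter shape mismatch for {key}")
                params[key].data = value.copy()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Conv2d(Module):
    """He-normal initialized square convolution (NCHW)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, (out_channels, in_channels, kernel_size, kernel_size)
        ).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(
            -bound, bound, (out_features, in_features)).astype(dtype))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features).astype(dtype))

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, *, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, training=self.training,
                            momentum=self.momentum, eps=self.eps)


class BatchNorm1d(BatchNorm2d):
    """Batch normalization over (B, C) vectors, sharing the fused kernel."""

    def forward(self, x):
        x4 = F.reshape(x, (x.shape[0], x.shape[1], 1, 1))
        y = super().forward(x4)
        return F.reshape(y, (x.shape[0], x.shape[1]))


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return F.maxpool2d(x, self.kernel_size, self.stride, self.padding)


class BConv(Module):
    """Convolution -> batch normalization -> ReLU composite.

    The convolution carries no bias; batch normalization's shift plays that
    role, as is conventional for conv+BN stacks.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, stride=stride,
                           padding=padding, dilation=dilation, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x):
        return F.relu(self.bn(self.conv(x)))


def global_avg_pool(x: Tensor) -> Tensor:
    """GAP over the spatial axes: (B, C, H, W) -> (B, C)."""
    return F.mean(x, axis=(2, 3))
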