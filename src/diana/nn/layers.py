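"""Network building blocks: modules, convolutions, normalization, SE and
inverted-residual blocks.

Initialization follows the common detection-network recipe (He-normal conv
weights, zero biases); the class-prediction layer can be given a prior-
probability bias so that training starts from a low foreground rate.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container with parameter discovery and train/eval mode."""

    def __init__(self):
        self._training = True

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _submodules(self):
        for val in vars(self).values():
            if isinstance(val, Module):
                yield val
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self._training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self):
        return self._training

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_buffers(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data[...] = arr
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = dilation * (k - 1) // 2
        fan_in = (c_in // groups) * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in // groups, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation,
                        groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean += m * (mu.data.ravel() - self.running_mean)
            self.running_var += m * (var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Swish(Module):
    def forward(self, x):
        return x * T.sigmoid(x)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class SqueezeExcite(Module):
    """Channel gate: global pool -> bottleneck MLP (as 1x1 convs) -> sigmoid scale."""

    def __init__(self, c: int, se_ratio: float = 0.25, rng=None):
        super().__init__()
        hidden = max(1, int(round(c * se_ratio)))
        self.reduce = Conv2d(c, hidden, k=1, padding=0, rng=rng)
        self.expand = Conv2d(hidden, c, k=1, padding=0, rng=rng)

    def forward(self, x):
        s = T.global_avg_pool(x)
        s = T.relu(self.reduce(s))
        gate = T.sigmoid(self.expand(s))
        return x * gate


class MBConv(Module):
    """Inverted residual block with squeeze-excitation (SE-MobileNetv2).

    expand (1x1) -> depthwise (3x3, stride) -> SE -> project (1x1), with a
    residual connection when stride is 1 and channel counts match.
    """

    def __init__(self, c_in: int, c_out: int, stride: int = 1, expansion: int = 4,
                 se_ratio: float = 0.25, rng=None):
        super().__init__()
        hidden = c_in * expansion
        self.expand = (Conv2d(c_in, hidden, k=1, padding=0, bias=False, rng=rng)
                       if expansion != 1 else None)
        self.bn0 = BatchNorm2d(hidden) if self.expand else None
        self.dw = Conv2d(hidden, hidden, k=3, stride=stride, groups=hidden,
                         bias=False, rng=rng)
        self.bn1 = BatchNorm2d(hidden)
        self.se = SqueezeExcite(hidden, se_ratio, rng=rng) if se_ratio > 0 else None
        self.project = Conv2d(hidden, c_out, k=1, padding=0, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.act = Swish()
        self.use_residual = stride == 1 and c_in == c_out

    def forward(self, x):
        h = x
        if self.expand is not None:
            h = self.act(self.bn0(self.expand(h)))
        h = self.act(self.bn1(self.dw(h)))
        if self.se is not None:
            h = self.se(h)
        h = self.bn2(self.project(h))
        if self.use_residual:
            h = h + x
        return h


class ConvBNAct(Module):
    def __init__(self, c_in, c_out, k=3, stride=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k=k, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.act = Swish() if act else None

    def forward(self, x):
        h = self.bn(self.conv(x))
        return self.act(h) if self.act else h


class DepthwiseSeparableConv(Module):
    """3x3 depthwise followed by 1x1 pointwise, BN + activation (BiFPN node conv)."""

    def __init__(self, c: int, rng=None):
        super().__init__()
        self.dw = Conv2d(c, c, k=3, groups=c, bias=False, rng=rng)
        self.pw = Conv2d(c, c, k=1, padding=0, bias=False, rng=rng)
        self.bn = BatchNorm2d(c)
        self.act = Swish()

    def forward(self, x):
        return self.act(self.bn(self.pw(self.dw(x))))
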