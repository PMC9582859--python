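"""Weighted bi-directional feature pyramid (BiFPN).

Each fusion node holds one learnable non-negative scalar per input edge;
fast normalized fusion rectifies the raw weights with ReLU and divides by
their sum plus a small epsilon, so the fusion coefficients lie in [0, 1]
and sum to (almost exactly) one.  The combined map then passes through a
depthwise-separable convolution.  Cross-scale resizing uses nearest-
neighbor upsampling on the way down in stride and stride-2 max pooling on
the way up; spatial resolution at every level is preserved end to end.

One BiFPN layer runs a top-down pass (levels 5..1) followed by a bottom-up
pass (levels 2..6); the layer is repeated ``repeats`` times.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T


class FusionNode(nn.Module):
    """Weighted fusion of same-shape maps followed by a node convolution."""

    def __init__(self, n_inputs: int, channels: int, eps: float = 1e-4, rng=None):
        super().__init__()
        self.edge_weights = nn.Parameter(np.ones(n_inputs, dtype=np.float32))
        self.eps = eps
        self.conv = nn.DepthwiseSeparableConv(channels, rng=rng)

    def combine(self, inputs: list) -> nn.Tensor:
        """Normalized weighted sum (the pre-convolution fusion)."""
        if len(inputs) != self.edge_weights.shape[0]:
            raise ValueError("edge count mismatch")
        w = T.relu(self.edge_weights)
        denom = w.sum() + self.eps
        out = inputs[0] * (w * _onehot(0, len(inputs))).sum() / denom
        for i, x in enumerate(inputs[1:], start=1):
            out = out + x * (w * _onehot(i, len(inputs))).sum() / denom
        return out

    def fusion_coefficients(self) -> np.ndarray:
        w = np.maximum(self.edge_weights.data, 0.0)
        return w / (w.sum() + self.eps)

    def forward(self, inputs: list) -> nn.Tensor:
        return self.conv(self.combine(inputs))


def _onehot(i: int, n: int) -> nn.Tensor:
    v = np.zeros(n, dtype=np.float32)
    v[i] = 1.0
    return nn.Tensor(v)


def fuse_node(node: FusionNode, inputs: list) -> nn.Tensor:
    return node(inputs)


class BiFPNLayer(nn.Module):
    """One top-down + bottom-up sweep over pyramid levels 1..6."""

    def __init__(self, channels: int, eps: float = 1e-4, rng=None):
        super().__init__()
        # top-down nodes for levels 5..1 (each fuses its input and the
        # upsampled coarser map); bottom-up nodes for levels 2..6
        self.td_nodes = [FusionNode(2, channels, eps, rng=rng) for _ in range(5)]
        # levels 2..5 fuse (input, td, downsampled finer output): 3 edges;
        # level 6 fuses (input, downsampled P5 output): 2 edges
        self.out_nodes = [FusionNode(3, channels, eps, rng=rng) for _ in range(4)]
        self.out_nodes.append(FusionNode(2, channels, eps, rng=rng))

    def forward(self, levels: dict) -> dict:
        td = {6: levels[6]}
        for l in range(5, 0, -1):
            up = T.upsample_nearest2d(td[l + 1], 2)
            td[l] = self.td_nodes[5 - l]([levels[l], up])
        out = {1: td[1]}
        for l in range(2, 6):
            down = T.max_pool2d(out[l - 1], 2)
            out[l] = self.out_nodes[l - 2]([levels[l], td[l], down])
        down = T.max_pool2d(out[5], 2)
        out[6] = self.out_nodes[4]([levels[6], down])
        return out


class BiFPN(nn.Module):
    """``repeats`` stacked BiFPN layers over reduced levels 1..6."""

    def __init__(self, channels: int, repeats: int, eps: float = 1e-4, rng=None):
        super().__init__()
        self.channels = channels
        self.layers = [BiFPNLayer(channels, eps, rng=rng) for _ in range(repeats)]

    def forward(self, reduced: dict) -> dict:
        for b in range(1, 7):
            if reduced[b].shape[1] != self.channels:
                raise ValueError(
                    f"level {b} has {reduced[b].shape[1]} channels, "
                    f"expected {self.channels}")
        levels = reduced
        for layer in self.layers:
            levels = layer(levels)
        return levels
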