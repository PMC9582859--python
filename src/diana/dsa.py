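"""Disease severity analyzer: a coupled encoder-decoder segmentation branch.

The encoder has four stages.  Stage 1 consumes the backbone stem output
C_0 concatenated with (a resize of) pyramid level P_1; stages 2..4 consume
the previous stage concatenated with the pyramid levels their coupling
strategy routes to them, pass through an SE-inverted-residual block and a
3x3 stride-2 convolution, halving the grid each time (strides 4, 8, 16, 32).

A parallel-dilation context module (PDC) probes the bottleneck at several
dilation rates; dense attention modules (DAM) gate the encoder->decoder
skips.  Each decoder stage bilinearly resizes the coarser operand up to the
skip's grid (this is the per-stage x2 upsampling), concatenates with the
gated skip, and applies an SE-inverted-residual block; the final map gets
``m_seg`` 3x3 convolutions, a prediction convolution with 11 severity
channels plus one background channel (softmax), and a x4 bilinear upsample
back to the input resolution.

Coupling strategies (which pyramid levels feed which encoder stage, summed
"+" or concatenated "(c)") are selectable; ``decoupled`` omits every pyramid
input and reduces the encoder to a plain convolutional pyramid over C_0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import tensor as T
from .core_io import N_STAGES


@dataclass(frozen=True)
class CouplingStrategy:
    name: str
    # encoder stage n (1..4) -> (tuple of pyramid levels, "sum" | "concat")
    routing: dict

    def levels_for(self, stage: int):
        return self.routing.get(stage, ((), "sum"))


_STRATEGIES = {
    "exp1": CouplingStrategy("exp1", {1: ((1,), "sum"), 2: ((2,), "sum"),
                                      3: ((3, 4), "sum"), 4: ((5, 6), "sum")}),
    "exp2": CouplingStrategy("exp2", {1: ((1,), "concat"), 2: ((2,), "concat"),
                                      3: ((3, 4), "concat"), 4: ((5, 6), "concat")}),
    "exp3": CouplingStrategy("exp3", {1: ((1,), "sum"), 2: ((2,), "sum"),
                                      3: ((3,), "sum"), 4: ((5,), "sum")}),
    "exp4": CouplingStrategy("exp4", {1: ((1,), "sum"), 2: ((2,), "sum"),
                                      3: ((4,), "sum"), 4: ((6,), "sum")}),
    "decoupled": CouplingStrategy("decoupled", {}),
}


def coupling_strategy(name: str) -> CouplingStrategy:
    try:
        return _STRATEGIES[name]
    except KeyError:
        raise KeyError(f"unknown coupling strategy {name!r}; "
                       f"choose from {sorted(_STRATEGIES)}") from None


@dataclass(frozen=True)
class DsaConfig:
    strategy: str = "exp4"
    encoder_widths: tuple = (24, 32, 48, 64)
    m_seg: int = 2
    n_stages: int = N_STAGES       # severity channels (background adds one)
    pdc_rates: tuple = (1, 2, 4, 8)
    pdc_width: int = 32
    dam_width: int = 16

    def __post_init__(self):
        if len(self.encoder_widths) != 4:
            raise ValueError("four encoder stages required")


def pyramid_routing_channels(strategy: CouplingStrategy, c_bifpn: int) -> list:
    """Extra input channels each encoder stage receives from the pyramid."""
    extras = []
    for n in range(1, 5):
        levels, mode = strategy.levels_for(n)
        if not levels:
            extras.append(0)
        elif mode == "concat":
            extras.append(c_bifpn * len(levels))
        else:
            extras.append(c_bifpn)
    return extras


class EncoderStage(nn.Module):
    """SE-inverted-residual block followed by a 3x3 stride-2 convolution."""

    def __init__(self, c_in: int, c_out: int, first: bool = False, rng=None):
        super().__init__()
        # stage 1 has no preceding encoder state: it is a single stride-2
        # convolution of C_0 (joined with P_1 when coupled)
        self.block = None if first else nn.MBConv(c_in, c_in, stride=1,
                                                  expansion=2, rng=rng)
        self.down = nn.ConvBNAct(c_in, c_out, k=3, stride=2, rng=rng)

    def forward(self, x):
        if self.block is not None:
            x = self.block(x)
        return self.down(x)


class PDC(nn.Module):
    """Parallel dilation convolution: dilated 3x3 branches, concatenated and
    fused by a 1x1 convolution; spatial size preserved."""

    def __init__(self, c_in: int, c_out: int, rates: tuple, width: int, rng=None):
        super().__init__()
        self.branches = [nn.Conv2d(c_in, width, k=3, dilation=r, rng=rng)
                         for r in rates]
        self.fuse = nn.Conv2d(width * len(rates), c_out, k=1, padding=0, rng=rng)
        self.act = nn.Swish()

    def forward(self, x):
        outs = [self.act(conv(x)) for conv in self.branches]
        return self.act(self.fuse(T.concat(outs, axis=1)))


class DAM(nn.Module):
    """Dense attention module: additive gate on a skip connection.

    1x1 projections of the skip and the (resized) gating signal are summed,
    passed through ReLU, projected to one channel and squashed to [0, 1];
    the skip is multiplied by the broadcast gate.
    """

    def __init__(self, c_skip: int, c_gate: int, width: int, rng=None):
        super().__init__()
        self.proj_skip = nn.Conv2d(c_skip, width, k=1, padding=0, rng=rng)
        self.proj_gate = nn.Conv2d(c_gate, width, k=1, padding=0, rng=rng)
        self.psi = nn.Conv2d(width, 1, k=1, padding=0, rng=rng)

    def gate(self, skip, gating):
        g = T.resize_bilinear(gating, (skip.shape[2], skip.shape[3]))
        h = T.relu(self.proj_skip(skip) + self.proj_gate(g))
        return T.sigmoid(self.psi(h))

    def forward(self, skip, gating):
        return skip * self.gate(skip, gating)


class DecoderStage(nn.Module):
    def __init__(self, c_coarse: int, c_skip: int, c_out: int, rng=None):
        super().__init__()
        self.block = nn.MBConv(c_coarse + c_skip, c_out, stride=1,
                               expansion=2, rng=rng)

    def forward(self, coarse, skip):
        up = T.resize_bilinear(coarse, (skip.shape[2], skip.shape[3]))
        return self.block(T.concat([up, skip], axis=1))


class DsaUnit(nn.Module):
    """Full severity branch; ``forward(C_0, pyramid)`` returns logits at the
    input resolution with ``n_stages + 1`` channels."""

    def __init__(self, c0_channels: int, c_bifpn: int, cfg: DsaConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        self.strategy = coupling_strategy(cfg.strategy)
        extras = pyramid_routing_channels(self.strategy, c_bifpn)
        w = cfg.encoder_widths
        ins = [c0_channels + extras[0]] + \
              [w[n - 2] + extras[n - 1] for n in range(2, 5)]
        self.encoder = [EncoderStage(ins[0], w[0], first=True, rng=rng)]
        self.encoder += [EncoderStage(ins[n - 1], w[n - 1], rng=rng)
                         for n in range(2, 5)]
        self.pdc = PDC(w[3], w[3], cfg.pdc_rates, cfg.pdc_width, rng=rng)
        self.dams = [DAM(w[n - 1], w[3] if n == 3 else w[n], cfg.dam_width, rng=rng)
                     for n in (3, 2, 1)]
        self.decoder = [
            DecoderStage(w[3], w[2], w[2], rng=rng),   # D_3
            DecoderStage(w[2], w[1], w[1], rng=rng),   # D_2
            DecoderStage(w[1], w[0], w[0], rng=rng),   # D_1
        ]
        self.head = [nn.ConvBNAct(w[0], w[0], k=3, rng=rng)
                     for _ in range(cfg.m_seg)]
        self.pred = nn.Conv2d(w[0], cfg.n_stages + 1, k=1, padding=0, rng=rng)
        self.invocations = 0  # pest-shortcut accounting

    def _join(self, base, pyramid: dict, stage: int):
        levels, mode = self.strategy.levels_for(stage)
        if not levels:
            return base
        hw = (base.shape[2], base.shape[3])
        maps = [T.resize_bilinear(pyramid[l], hw) for l in levels]
        if mode == "sum":
            combined = maps[0]
            for m in maps[1:]:
                combined = combined + m
            maps = [combined]
        return T.concat([base] + maps, axis=1)

    def encode(self, c0, pyramid: dict) -> list:
        stages = []
        h = self._join(c0, pyramid, 1)
        h = self.encoder[0](h)
        stages.append(h)
        for n in range(2, 5):
            h = self._join(h, pyramid, n)
            h = self.encoder[n - 1](h)
            stages.append(h)
        return stages

    def decode(self, stages: list, out_hw: tuple) -> nn.Tensor:
        e1, e2, e3, e4 = stages
        d = self.pdc(e4)                        # D_4
        for dam, dec, skip in zip(self.dams, self.decoder, (e3, e2, e1)):
            gated = dam(skip, d)
            d = dec(d, gated)                   # D_3, D_2, D_1
        for conv in self.head:
            d = conv(d)
        logits = self.pred(d)
        return T.resize_bilinear(logits, out_hw)

    def forward(self, c0, pyramid: dict, out_hw: tuple) -> nn.Tensor:
        self.invocations += 1
        return self.decode(self.encode(c0, pyramid), out_hw)


# -- loss ----------------------------------------------------------------------

def focal_tversky_loss(probs: nn.Tensor, target_onehot: np.ndarray,
                       alpha: float = 0.3, beta: float = 0.7,
                       gamma: float = 4.0, smooth: float = 1e-6) -> nn.Tensor:
    """Focal-Tversky loss over per-pixel class probabilities.

    Per class c: TI_c = (TP + s) / (TP + alpha*FP + beta*FN + s) on soft
    counts; the loss is sum_c (1 - TI_c)^(1/gamma).  alpha weights false
    positives, beta false negatives (beta > alpha penalizes missed lesion
    pixels harder); the smoothing term makes classes absent from both sides
    contribute zero.

    ``probs``: (N, C, H, W) softmax probabilities; ``target_onehot`` same
    shape, one-hot over C = n_stages + 1 (background channel 0).
    """
    y = nn.Tensor(target_onehot.astype(np.float32))
    axes = (0, 2, 3)
    tp = (probs * y).sum(axis=axes)
    fp = (probs * (1.0 - y)).sum(axis=axes)
    fn = ((1.0 - probs) * y).sum(axis=axes)
    ti = (tp + smooth) / (tp + alpha * fp + beta * fn + smooth)
    diff = 1.0 - ti
    # the fractional power has an unbounded derivative at 0: evaluate it on
    # a floored copy and hard-zero the (already converged) classes below the
    # floor, so perfectly absent or perfectly predicted classes contribute
    # exactly 0 with finite gradients
    floor = 1e-6
    powed = T.clip(diff, floor, 1.0) ** (1.0 / gamma)
    return T.where_mask(diff.data > floor, powed, diff * 0.0).sum()


def mask_to_onehot(mask: np.ndarray, n_stages: int = N_STAGES) -> np.ndarray:
    """H x W stage mask -> (n_stages+1, H, W) one-hot with background 0."""
    return (np.arange(n_stages + 1)[:, None, None] == mask[None]).astype(np.float32)
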