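"""Compound-scaled convolutional backbone emitting seven feature levels.

The extractor is a stack of squeeze-excitation inverted-residual (MBConv)
blocks.  Level C_0 is the stem convolution output at stride 2; levels
C_1..C_6 are six successive block groups whose cumulative strides double
strictly (2, 4, 8, 16, 32, 64), so each level maps one-to-one onto a
pyramid level.  Channel widths scale with ``width_mult`` (rounded to
multiples of 8, never below 90% of the requested width) and group depths
with ``depth_mult`` (ceiling).

Two presets are provided: ``b3`` — a B3-like budget (width 1.2, depth 1.4)
— and ``tiny``, the CPU-scale test workhorse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn


def round_channels(c: float, divisor: int = 8) -> int:
    """EfficientNet-style width rounding: to the nearest multiple of
    ``divisor`` but never below 90% of the unrounded value."""
    rounded = max(divisor, int(c + divisor / 2) // divisor * divisor)
    if rounded < 0.9 * c:
        rounded += divisor
    return rounded


@dataclass(frozen=True)
class BlockSpec:
    repeats: int
    channels: int
    stride: int        # stride of the group's first block
    expansion: int
    se_ratio: float = 0.25


@dataclass(frozen=True)
class BackboneConfig:
    stem_channels: int = 32
    width_mult: float = 1.0
    depth_mult: float = 1.0
    block_specs: tuple = (
        BlockSpec(2, 16, 1, 1),
        BlockSpec(2, 24, 2, 6),
        BlockSpec(3, 48, 2, 6),
        BlockSpec(3, 96, 2, 6),
        BlockSpec(4, 136, 2, 6),
        BlockSpec(2, 232, 2, 6),
    )

    def __post_init__(self):
        if len(self.block_specs) != 6:
            raise ValueError("exactly six block groups (C_1..C_6) are required")

    def scaled_channels(self) -> list:
        """Output channels of C_0..C_6 after width scaling and rounding."""
        chans = [round_channels(self.stem_channels * self.width_mult)]
        chans += [round_channels(s.channels * self.width_mult)
                  for s in self.block_specs]
        return chans

    def scaled_repeats(self) -> list:
        return [max(1, math.ceil(s.repeats * self.depth_mult))
                for s in self.block_specs]

    def level_strides(self) -> list:
        """Cumulative stride of C_0..C_6 relative to the input."""
        strides = [2]
        s = 2
        for spec in self.block_specs:
            s *= spec.stride
            strides.append(s)
        return strides


def backbone_preset(name: str) -> BackboneConfig:
    if name == "b3":
        return BackboneConfig(width_mult=1.2, depth_mult=1.4)
    if name == "tiny":
        return BackboneConfig(
            stem_channels=8, width_mult=1.0, depth_mult=1.0,
            block_specs=(
                BlockSpec(1, 8, 1, 1),
                BlockSpec(1, 16, 2, 2),
                BlockSpec(1, 16, 2, 2),
                BlockSpec(1, 24, 2, 2),
                BlockSpec(1, 24, 2, 2),
                BlockSpec(1, 32, 2, 2),
            ))
    raise KeyError(f"unknown backbone preset {name!r}")


class Backbone(nn.Module):
    """Feature extractor; ``forward`` returns the dict {0..6} -> level map."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        chans = cfg.scaled_channels()
        repeats = cfg.scaled_repeats()
        self.stem = nn.ConvBNAct(3, chans[0], k=3, stride=2, rng=rng)
        self.groups = []
        c_in = chans[0]
        for spec, c_out, reps in zip(cfg.block_specs, chans[1:], repeats):
            blocks = []
            for r in range(reps):
                blocks.append(nn.MBConv(
                    c_in, c_out, stride=spec.stride if r == 0 else 1,
                    expansion=spec.expansion, se_ratio=spec.se_ratio, rng=rng))
                c_in = c_out
            self.groups.append(nn.Sequential(*blocks))

    def forward(self, x: nn.Tensor) -> dict:
        h, w = x.shape[2], x.shape[3]
        total = self.cfg.level_strides()[-1]
        if h % total or w % total:
            raise ValueError(
                f"input {h}x{w} not divisible by the total stride {total}; "
                f"pad to {math.ceil(h / total) * total}x"
                f"{math.ceil(w / total) * total}")
        levels = {}
        h = self.stem(x)
        levels[0] = h
        for b, group in enumerate(self.groups, start=1):
            h = group(h)
            levels[b] = h
        return levels


class ChannelReducer(nn.Module):
    """Single 3x3 stride-1 convolutions mapping C_1..C_6 to a constant
    ``c_bifpn`` channel count (C_0 is left untouched: it feeds the severity
    encoder directly)."""

    def __init__(self, backbone_channels: list, c_bifpn: int, rng=None):
        super().__init__()
        self.convs = [nn.Conv2d(c, c_bifpn, k=3, rng=rng)
                      for c in backbone_channels[1:]]

    def forward(self, levels: dict) -> dict:
        return {b: self.convs[b - 1](levels[b]) for b in range(1, 7)}
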