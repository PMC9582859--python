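"""The joint detection + severity model: backbone, channel reduction, BiFPN,
class/box subnetworks and the (optionally decoupled) severity branch, with
presets mirroring the published configuration (``paper``) and a CPU-scale
``tiny`` configuration used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .backbone import Backbone, BackboneConfig, ChannelReducer, backbone_preset
from .bifpn import BiFPN
from .detection import (DetectionHeadConfig, class_subnet, box_subnet,
                        generate_anchors)
from .dsa import DsaConfig, DsaUnit
from .nn import tensor as T


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=lambda: backbone_preset("b3"))
    c_bifpn: int = 224
    m_bifpn: int = 3
    head: DetectionHeadConfig = field(default_factory=DetectionHeadConfig)
    dsa: DsaConfig | None = field(default_factory=DsaConfig)
    dropout: float = 0.3
    seed: int = 0

    def with_strategy(self, name: str) -> "ModelConfig":
        if name == "detector-only":
            return replace(self, dsa=None)
        return replace(self, dsa=replace(self.dsa or DsaConfig(), strategy=name))


def model_preset(name: str) -> ModelConfig:
    if name == "paper":
        return ModelConfig()
    if name == "tiny":
        return ModelConfig(
            backbone=backbone_preset("tiny"),
            c_bifpn=16,
            m_bifpn=1,
            head=DetectionHeadConfig(m_class=1, m_box=1),
            dsa=DsaConfig(encoder_widths=(16, 24, 32, 40),
                          pdc_rates=(1, 2, 4), pdc_width=16, dam_width=8),
            dropout=0.0,
        )
    raise KeyError(f"unknown model preset {name!r}")


class DianaModel(nn.Module):
    """End-to-end trainable detector + severity analyzer."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 77]))
        self.cfg = cfg
        self.backbone = Backbone(cfg.backbone, rng=rng)
        chans = cfg.backbone.scaled_channels()
        self.reducer = ChannelReducer(chans, cfg.c_bifpn, rng=rng)
        self.bifpn = BiFPN(cfg.c_bifpn, cfg.m_bifpn, rng=rng)
        self.cls_net = class_subnet(cfg.head, cfg.c_bifpn,
                                    dropout=cfg.dropout, rng=rng)
        self.box_net = box_subnet(cfg.head, cfg.c_bifpn, rng=rng)
        self.dsa = (DsaUnit(chans[0], cfg.c_bifpn, cfg.dsa, rng=rng)
                    if cfg.dsa is not None else None)

    # -- forward pieces ----------------------------------------------------
    def forward_features(self, x: nn.Tensor):
        levels = self.backbone(x)
        pyramid = self.bifpn(self.reducer(levels))
        return levels[0], pyramid

    def forward_detection(self, pyramid: dict):
        """Per-level raw outputs concatenated over levels 1..6:
        class logits (N, A, N_cls) and box deltas (N, A, 4)."""
        cls_out = T.concat([self.cls_net(pyramid[l]) for l in range(1, 7)], axis=1)
        box_out = T.concat([self.box_net(pyramid[l]) for l in range(1, 7)], axis=1)
        return cls_out, box_out

    def forward_dsa(self, c0, pyramid: dict, out_hw: tuple):
        if self.dsa is None:
            raise RuntimeError("model was built detector-only")
        return self.dsa(c0, pyramid, out_hw)

    def forward(self, x: nn.Tensor, with_dsa: bool = True) -> dict:
        c0, pyramid = self.forward_features(x)
        cls_out, box_out = self.forward_detection(pyramid)
        out = {"cls_logits": cls_out, "box_deltas": box_out, "pyramid": pyramid,
               "c0": c0}
        if with_dsa and self.dsa is not None:
            out["seg_logits"] = self.forward_dsa(
                c0, pyramid, (x.shape[2], x.shape[3]))
        return out

    # -- geometry ------------------------------------------------------------
    def pyramid_shapes(self, image_hw: tuple) -> dict:
        h, w = image_hw
        strides = self.level_strides()
        return {l: (h // strides[l], w // strides[l]) for l in range(1, 7)}

    def level_strides(self) -> dict:
        s = self.cfg.backbone.level_strides()
        return {l: s[l] for l in range(0, 7)}

    def anchors_for(self, image_hw: tuple) -> np.ndarray:
        per_level = generate_anchors(self.pyramid_shapes(image_hw),
                                     self.level_strides(), self.cfg.head)
        return np.concatenate([per_level[l] for l in range(1, 7)], axis=0)
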