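"""Configuration plumbing: preset inheritance, YAML overrides and
(de)serialization of the model/training dataclasses for checkpoints.

A YAML config may set ``preset: tiny|paper`` and then override any field
under the ``backbone:``, ``fpn:``, ``head:``, ``dsa:``, ``train:`` or
``data:`` sections.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path

import yaml

from .backbone import BackboneConfig, BlockSpec
from .detection import DetectionHeadConfig
from .dsa import DsaConfig
from .model import ModelConfig, model_preset
from .synthetic import SceneConfig
from .train import TrainConfig, train_preset


def model_config_to_dict(cfg: ModelConfig) -> dict:
    return asdict(cfg)


def model_config_from_dict(d: dict) -> ModelConfig:
    backbone = d["backbone"]
    specs = tuple(BlockSpec(**s) for s in backbone["block_specs"])
    bcfg = BackboneConfig(stem_channels=backbone["stem_channels"],
                          width_mult=backbone["width_mult"],
                          depth_mult=backbone["depth_mult"],
                          block_specs=specs)
    head = DetectionHeadConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in d["head"].items()})
    dsa = None
    if d.get("dsa") is not None:
        dsa = DsaConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d["dsa"].items()})
    return ModelConfig(backbone=bcfg, c_bifpn=d["c_bifpn"],
                       m_bifpn=d["m_bifpn"], head=head, dsa=dsa,
                       dropout=d["dropout"], seed=d["seed"])


def train_config_to_dict(cfg: TrainConfig) -> dict:
    return asdict(cfg)


def train_config_from_dict(d: dict) -> TrainConfig:
    return TrainConfig(**d)


def load_config(path=None, preset: str = "tiny", overrides: dict | None = None):
    """Resolve (ModelConfig, TrainConfig, SceneConfig) from a preset plus an
    optional YAML file plus explicit overrides (highest precedence)."""
    doc = {}
    if path is not None:
        with open(Path(path)) as fh:
            doc = yaml.safe_load(fh) or {}
    preset = doc.get("preset", preset)
    model_cfg = model_preset(preset)
    train_cfg = train_preset(preset)
    scene_cfg = SceneConfig()

    def apply(obj, section):
        vals = {**doc.get(section, {}), **(overrides or {}).get(section, {})}
        return replace(obj, **vals) if vals else obj

    model_cfg = apply(model_cfg, "model")
    if "fpn" in doc:
        fpn = doc["fpn"]
        model_cfg = replace(model_cfg,
                            c_bifpn=fpn.get("channels", model_cfg.c_bifpn),
                            m_bifpn=fpn.get("repeats", model_cfg.m_bifpn))
    if "head" in doc:
        model_cfg = replace(model_cfg, head=replace(model_cfg.head, **doc["head"]))
    if "dsa" in doc and model_cfg.dsa is not None:
        dsa_over = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in doc["dsa"].items()}
        model_cfg = replace(model_cfg, dsa=replace(model_cfg.dsa, **dsa_over))
    train_cfg = apply(train_cfg, "train")
    if "data" in doc:
        data_over = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in doc["data"].items()}
        scene_cfg = replace(scene_cfg, **data_over)
    return model_cfg, train_cfg, scene_cfg
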