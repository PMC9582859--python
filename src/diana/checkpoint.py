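"""Checkpoint archive: model weights, normalization statistics, optimizer
state and the full configuration in a single ``.npz`` file."""

from __future__ import annotations

import json

import numpy as np

from .config import (model_config_from_dict, model_config_to_dict,
                     train_config_from_dict, train_config_to_dict)
from .model import DianaModel


def save_checkpoint(path, model: DianaModel, ckpt: dict,
                    train_cfg=None) -> None:
    meta = {"model": model_config_to_dict(model.cfg),
            "train": train_config_to_dict(train_cfg) if train_cfg else None,
            "step": int(ckpt.get("step", 0))}
    arrays = {f"state/{k}": v for k, v in ckpt["state"].items()}
    for i, v in enumerate(ckpt.get("velocity", [])):
        arrays[f"velocity/{i}"] = v
    np.savez(path, norm_mean=ckpt["norm_mean"], norm_std=ckpt["norm_std"],
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Returns (model in eval mode, norm_mean, norm_std, meta dict)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model = DianaModel(model_config_from_dict(meta["model"]))
        state = {k[len("state/"):]: data[k] for k in data.files
                 if k.startswith("state/")}
        model.load_state_dict(state)
        model.eval()
        norm_mean = data["norm_mean"]
        norm_std = data["norm_std"]
    if meta.get("train"):
        meta["train_cfg"] = train_config_from_dict(meta["train"])
    return model, norm_mean, norm_std, meta
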