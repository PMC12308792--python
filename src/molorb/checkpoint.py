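"""Versioned JSON checkpoints for models and ensembles.

Weights are serialized as nested lists via ``repr``-faithful JSON floats, so
a save/load round trip reproduces every float64 bit-exactly.  Format:

    {"format": "molorb-checkpoint", "version": 1, "kind": "model" | "ensemble",
     ...}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ensemble import Ensemble
from .fingerprint import FingerprintConfig, FingerprintParams
from .regressor import Hyperparameters, TrainedModel, TrainingHistory

FORMAT = "molorb-checkpoint"
VERSION = 1


def _weights_to_json(weights: dict[str, np.ndarray]) -> dict:
    return {k: v.tolist() for k, v in weights.items()}


def _weights_from_json(obj: dict) -> dict[str, np.ndarray]:
    return {k: np.array(v, dtype=np.float64) for k, v in obj.items()}


def model_to_dict(model: TrainedModel) -> dict:
    h = model.history
    return {
        "format": FORMAT,
        "version": VERSION,
        "kind": "model",
        "target": model.target,
        "hyper": model.hyper.__dict__,
        "fp_config": model.fp_params.config.__dict__,
        "y_mean": model.y_mean,
        "y_std": model.y_std,
        "history": {
            "train_loss": h.train_loss,
            "val_loss": h.val_loss,
            "stopped_epoch": h.stopped_epoch,
            "stop_reason": h.stop_reason,
        },
        "weights": _weights_to_json(model.weights),
    }


def model_from_dict(obj: dict) -> TrainedModel:
    if obj.get("format") != FORMAT or obj.get("kind") != "model":
        raise ValueError("not a molorb model checkpoint")
    if obj.get("version") != VERSION:
        raise ValueError(f"unsupported checkpoint version {obj.get('version')}")
    hyper = Hyperparameters(**obj["hyper"])
    config = FingerprintConfig(**obj["fp_config"])
    params = FingerprintParams(
        config=config, weights=_weights_from_json(obj["weights"])
    )
    hist = TrainingHistory(**obj["history"])
    return TrainedModel(
        target=obj["target"],
        hyper=hyper,
        fp_params=params,
        y_mean=obj["y_mean"],
        y_std=obj["y_std"],
        history=hist,
    )


def save_model(model: TrainedModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path) -> TrainedModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_ensemble(ens: Ensemble, path) -> None:
    obj = {
        "format": FORMAT,
        "version": VERSION,
        "kind": "ensemble",
        "target": ens.target,
        "combiner_weights": ens.combiner_weights.tolist(),
        "combiner_bias": ens.combiner_bias,
        "combiner_epochs": ens.combiner_epochs,
        "members": [model_to_dict(m) for m in ens.members],
    }
    Path(path).write_text(json.dumps(obj))


def load_ensemble(path) -> Ensemble:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != FORMAT or obj.get("kind") != "ensemble":
        raise ValueError("not a molorb ensemble checkpoint")
    return Ensemble(
        members=[model_from_dict(m) for m in obj["members"]],
        combiner_weights=np.array(obj["combiner_weights"], dtype=np.float64),
        combiner_bias=obj["combiner_bias"],
        combiner_epochs=obj["combiner_epochs"],
        target=obj["target"],
    )
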