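"""Checkpointing for trained classifiers (numpy .npz, self-describing)."""

from __future__ import annotations

import json

import numpy as np

from .architecture import default_model_spec
from .augment import AugmentationConfig
from .classifier import SpheroidCNNClassifier
from .nn import network_from_spec

__all__ = ["save_model", "load_model"]


def save_model(est: SpheroidCNNClassifier, path: str) -> None:
    """Persist a fitted `SpheroidCNNClassifier` to a .npz checkpoint."""
    if not hasattr(est, "model_"):
        raise ValueError("estimator is not fitted")
    weights = est.model_.get_weights()
    params = est.get_params()
    aug = params.pop("augmentation")
    meta = {
        "params": params,
        "augmentation": None if aug is None else aug.__dict__,
        "classes": [str(c) for c in est.classes_],
        "input_shape": list(est.model_spec_.input_shape),
        "dropout": est.dropout,
    }
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> SpheroidCNNClassifier:
    """Restore a checkpoint written by `save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    aug = meta["augmentation"]
    est = SpheroidCNNClassifier(
        augmentation=None if aug is None else AugmentationConfig(**aug), **meta["params"]
    )
    spec = default_model_spec(
        input_shape=tuple(meta["input_shape"]),
        n_classes=len(meta["classes"]),
        dropout_rate=meta["dropout"],
    )
    est.model_spec_ = spec
    est.model_ = network_from_spec(spec, seed=0, learning_rate=est.learning_rate)
    est.model_.set_weights(weights)
    est.classes_ = np.array(meta["classes"])
    est.n_parameters_ = est.model_.n_parameters
    est.history_ = {}
    return est
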