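"""HDF5 checkpointing: weights + config + training history in one .h5 file."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .net import RestorationModel, RUNetConfig, build_runet

__all__ = ["save_model", "load_model"]


def save_model(model: RestorationModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(
            {
                "depth": model.config.depth,
                "base_channels": model.config.base_channels,
                "epochs": model.config.epochs,
                "batch_size": model.config.batch_size,
                "learning_rate": model.config.learning_rate,
                "loss_weights": model.config.loss_weights,
                "global_residual": model.config.global_residual,
                "seed": model.config.seed,
            }
        )
        g = f.create_group("weights")
        for name, arr in model.net.get_weights().items():
            g.create_dataset(name, data=arr)
        h = f.create_group("history")
        hist = model.training_history
        h.create_dataset("epoch", data=np.array([e["epoch"] for e in hist], dtype=np.int64))
        h.create_dataset("train_loss", data=np.array([e["train_loss"] for e in hist]))
        h.create_dataset("val_loss", data=np.array([e["val_loss"] for e in hist]))


def _visit_datasets(group: h5py.Group) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}

    def cb(name, obj):
        if isinstance(obj, h5py.Dataset):
            out[name] = obj[()]

    group.visititems(cb)
    return out


def load_model(path) -> RestorationModel:
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        model = build_runet(RUNetConfig(**cfg))
        model.net.set_weights(_visit_datasets(f["weights"]))
        h = f["history"]
        model.training_history = [
            {"epoch": int(e), "train_loss": float(t), "val_loss": float(v)}
            for e, t, v in zip(h["epoch"][()], h["train_loss"][()], h["val_loss"][()])
        ]
    return model
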