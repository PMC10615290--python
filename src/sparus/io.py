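"""Serialization: RF channel data and paired datasets to HDF5, B-mode
frames to 8-bit grayscale PNG/TIFF, configs to YAML."""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml
from PIL import Image

from .acquisition import RFChannelData
from .beamform import BModeImage, ImageGrid
from .phantoms import PairedDataset

__all__ = [
    "save_rf",
    "load_rf",
    "save_bmode_png",
    "load_bmode_png",
    "save_paired_dataset",
    "load_paired_dataset",
    "load_yaml",
    "save_yaml",
]


def save_rf(rf: RFChannelData, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rf.traces)
        f.create_dataset("t0", data=rf.t0)
        f.create_dataset("sampling_rate", data=rf.sampling_rate)
        for group in ("array", "sequence"):
            g = f.create_group(group)
            for k, v in rf.provenance.get(group, {}).items():
                g.attrs[k] = json.dumps(v) if isinstance(v, (list, dict)) else v


def load_rf(path) -> RFChannelData:
    with h5py.File(path, "r") as f:
        prov = {}
        for group in ("array", "sequence"):
            if group in f:
                prov[group] = {
                    k: json.loads(v) if isinstance(v, str) and v[:1] in "[{" else v
                    for k, v in f[group].attrs.items()
                }
        return RFChannelData(
            traces=f["traces"][()],
            t0=float(f["t0"][()]),
            sampling_rate=float(f["sampling_rate"][()]),
            provenance=prov,
        )


def save_bmode_png(image: BModeImage, path) -> None:
    Image.fromarray(image.pixels, mode="L").save(path)


def load_bmode_png(path, grid: ImageGrid | None = None, dynamic_range_db: float = 50.0) -> BModeImage:
    px = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    if grid is None:
        grid = ImageGrid(n_rows=px.shape[0], n_cols=px.shape[1])
    return BModeImage(px, grid, dynamic_range_db, {"source": str(path)})


def _grid_meta(grid: ImageGrid) -> dict:
    return {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "lateral_min": grid.lateral_min,
        "lateral_max": grid.lateral_max,
        "depth_min": grid.depth_min,
        "depth_max": grid.depth_max,
    }


def save_paired_dataset(data: PairedDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = data.seed
        f.attrs["metadata"] = json.dumps(data.metadata)
        f.attrs["split"] = json.dumps(data.split)
        grid = data.dense_images[0].grid
        f.attrs["grid"] = json.dumps(_grid_meta(grid))
        f.attrs["dynamic_range_db"] = data.dense_images[0].dynamic_range_db
        f.create_dataset(
            "dense", data=np.stack([im.pixels for im in data.dense_images])
        )
        g = f.create_group("sparse")
        for factor, imgs in data.sparse_images.items():
            g.create_dataset(str(factor), data=np.stack([im.pixels for im in imgs]))


def load_paired_dataset(path) -> PairedDataset:
    with h5py.File(path, "r") as f:
        grid = ImageGrid(**json.loads(f.attrs["grid"]))
        dr = float(f.attrs["dynamic_range_db"])
        dense = [BModeImage(px, grid, dr) for px in f["dense"][()]]
        sparse = {
            int(k): [BModeImage(px, grid, dr) for px in ds[()]]
            for k, ds in f["sparse"].items()
        }
        return PairedDataset(
            dense_images=dense,
            sparse_images=sparse,
            split=json.loads(f.attrs["split"]),
            seed=int(f.attrs["seed"]),
            metadata=json.loads(f.attrs["metadata"]),
        )


def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def save_yaml(obj: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=True)
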