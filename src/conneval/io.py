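"""Reading and writing label volumes, synapse lists, and ROI specs.

Label volumes are stored as a single chunked integer dataset named
``labels`` in either HDF5 (``.h5``/``.hdf5``) or zarr (``.zarr``), with
``offset`` and ``resolution`` attributes.  Synapse lists are JSON
(``[{"id": ..., "pre": [z,y,x], "post": [z,y,x]}, ...]``) or CSV/TSV with
columns ``pre_z,pre_y,pre_x,post_z,post_y,post_x`` (an optional ``id``
column is honoured).  An ROI is JSON with a block shape and explicit block
indices.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
import zarr

from .core import GridSpec, LabelVolume, SynapseConnection

__all__ = [
    "read_volume",
    "write_volume",
    "read_synapses",
    "write_synapses",
    "read_roi",
    "write_roi",
]

_DATASET = "labels"


def _is_zarr(path: str) -> bool:
    return str(path).rstrip("/").endswith(".zarr")


def write_volume(path: str, volume: LabelVolume, chunks: tuple[int, int, int] | None = None) -> None:
    chunks = chunks or tuple(min(64, s) for s in volume.shape)
    if _is_zarr(path):
        root = zarr.open_group(path, mode="w")
        arr = root.create_array(_DATASET, shape=volume.shape, dtype=volume.data.dtype, chunks=chunks)
        arr[:] = volume.data
        arr.attrs["offset"] = list(volume.offset)
        arr.attrs["resolution"] = list(volume.resolution)
    else:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(_DATASET, data=volume.data, chunks=chunks)
            ds.attrs["offset"] = list(volume.offset)
            ds.attrs["resolution"] = list(volume.resolution)


def read_volume(path: str) -> LabelVolume:
    if _is_zarr(path):
        root = zarr.open_group(path, mode="r")
        ds = root[_DATASET]
        data = np.asarray(ds[:])
        offset = tuple(ds.attrs.get("offset", (0, 0, 0)))
        resolution = tuple(ds.attrs.get("resolution", (1.0, 1.0, 1.0)))
    else:
        with h5py.File(path, "r") as f:
            ds = f[_DATASET]
            data = ds[:]
            offset = tuple(ds.attrs.get("offset", (0, 0, 0)))
            resolution = tuple(ds.attrs.get("resolution", (1.0, 1.0, 1.0)))
    return LabelVolume(data, offset=offset, resolution=resolution)


def write_synapses(path: str, connections: Iterable[SynapseConnection]) -> None:
    records = [
        {"id": c.id, "pre": list(c.pre), "post": list(c.post)} for c in connections
    ]
    with open(path, "w") as f:
        json.dump(records, f, indent=1)


def read_synapses(path: str) -> list[SynapseConnection]:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".json":
        with open(path) as f:
            records = json.load(f)
        return [
            SynapseConnection(pre=tuple(r["pre"]), post=tuple(r["post"]), id=r.get("id", i))
            for i, r in enumerate(records)
        ]
    sep = "\t" if ext in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    required = ["pre_z", "pre_y", "pre_x", "post_z", "post_y", "post_x"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"synapse table {path} missing columns {missing}")
    ids = df["id"] if "id" in df.columns else df.index
    return [
        SynapseConnection(
            pre=(row.pre_z, row.pre_y, row.pre_x),
            post=(row.post_z, row.post_y, row.post_x),
            id=i,
        )
        for i, (_, row) in zip(ids, df.iterrows())
    ]


def write_roi(path: str, grid: GridSpec) -> None:
    payload = {
        "block_shape": list(grid.block_shape),
        "origin": list(grid.origin),
        "blocks": [list(b) for b in grid.sorted_blocks()],
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def read_roi(path: str) -> GridSpec:
    with open(path) as f:
        payload = json.load(f)
    return GridSpec(
        block_shape=tuple(payload["block_shape"]),
        roi_blocks=frozenset(tuple(b) for b in payload["blocks"]),
        origin=tuple(payload.get("origin", (0, 0, 0))),
    )
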