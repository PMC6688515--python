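"""HDF5 container for labeled datasets and continuous recordings.

Dataset layout: /epochs (float32, epoch x channel x sample), /labels/z,
/labels/y (optional), /rejected_mask, and /meta — a JSON-encoded string
holding the configuration (band, window, thresholds, seeds, manifest).
Recording layout: /X (channel x sample), /fs, /channel_names, /meta.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np

from .labeling import EpochedDataset, LabelSet
from .synthgen import ContinuousRecording

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_recording",
    "load_recording",
]


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def save_dataset(path: str | os.PathLike, ds: EpochedDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=ds.epochs.astype(np.float32))
        f.create_dataset("rejected_mask", data=ds.rejected_mask)
        lab = f.create_group("labels")
        if ds.labels.z_epoch is not None:
            lab.create_dataset("z", data=ds.labels.z_epoch)
        if ds.labels.y_epoch is not None:
            lab.create_dataset("y", data=ds.labels.y_epoch)
        if ds.labels.z_cont is not None:
            lab.create_dataset("z_cont", data=ds.labels.z_cont)
        meta = {
            "fs": ds.fs,
            "dataset_meta": ds.meta,
            "label_meta": ds.labels.meta,
            "target_source": ds.labels.target_source,
            "band_hz": ds.labels.band_hz,
            "tertile": ds.labels.tertile,
        }
        f.create_dataset("meta", data=json.dumps(meta, default=_json_default))


def load_dataset(path: str | os.PathLike) -> EpochedDataset:
    with h5py.File(path, "r") as f:
        meta = json.loads(f["meta"][()].decode())
        labels = LabelSet(
            z_epoch=np.asarray(f["labels/z"]) if "labels/z" in f else None,
            y_epoch=np.asarray(f["labels/y"]) if "labels/y" in f else None,
            z_cont=np.asarray(f["labels/z_cont"]) if "labels/z_cont" in f else None,
            target_source=meta.get("target_source"),
            band_hz=tuple(meta["band_hz"]) if meta.get("band_hz") else None,
            tertile=meta.get("tertile"),
            meta=meta.get("label_meta", {}),
        )
        return EpochedDataset(
            epochs=np.asarray(f["epochs"], dtype=float),
            labels=labels,
            rejected_mask=np.asarray(f["rejected_mask"], dtype=bool),
            fs=float(meta["fs"]),
            meta=meta.get("dataset_meta", {}),
        )


def save_recording(path: str | os.PathLike, rec: ContinuousRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=rec.X)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "channel_names",
            data=np.array(rec.channel_names, dtype=h5py.string_dtype()),
        )
        f.create_dataset("meta", data=json.dumps(rec.meta, default=_json_default))


def load_recording(path: str | os.PathLike) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in np.asarray(f["channel_names"])
        ]
        return ContinuousRecording(
            X=np.asarray(f["X"], dtype=float),
            fs=float(f["fs"][()]),
            channel_names=names,
            meta=json.loads(f["meta"][()].decode()) if "meta" in f else {},
        )
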