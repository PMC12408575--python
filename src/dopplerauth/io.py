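"""Artifact persistence: HDF5 datasets, model checkpoints, galleries.

Every artifact embeds the config hash and seed that produced it so a run can
be traced back to its configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from dopplerauth.auth import GalleryEntry, SubjectGallery
from dopplerauth.preprocess import BeatSegment
from dopplerauth.wavelet import BeatSpectrogram

__all__ = [
    "save_segments",
    "load_segments",
    "save_spectrograms",
    "load_spectrograms",
    "save_model",
    "load_model_arrays",
    "save_gallery",
    "load_gallery",
]


def save_segments(
    segments: list[BeatSegment], path: str | Path,
    config_hash: str = "", seed: int = 0,
) -> None:
    """Persist gated beat segments: sample matrix, SNRs, ids, split tags."""
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["seed"] = seed
        f.create_dataset("samples", data=np.stack([s.samples for s in segments]))
        f.create_dataset("snr", data=[s.snr for s in segments])
        f.create_dataset("subject_id", data=[s.subject_id for s in segments])
        f.create_dataset("center_index", data=[s.center_index for s in segments])
        f.create_dataset(
            "split_tag", data=np.array([s.split_tag for s in segments], dtype="S8")
        )


def load_segments(path: str | Path) -> list[BeatSegment]:
    with h5py.File(path, "r") as f:
        samples = f["samples"][...]
        snr = f["snr"][...]
        sids = f["subject_id"][...]
        centers = f["center_index"][...]
        tags = [t.decode() for t in f["split_tag"][...]]
    return [
        BeatSegment(int(s), int(c), x, snr=float(r), split_tag=t)
        for x, r, s, c, t in zip(samples, snr, sids, centers, tags)
    ]


def save_spectrograms(
    items: list[BeatSpectrogram], path: str | Path,
    config_hash: str = "", seed: int = 0,
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["seed"] = seed
        f.create_dataset("values", data=np.stack([s.values for s in items]))
        f.create_dataset("subject_id", data=[s.subject_id for s in items])
        f.create_dataset("order", data=[s.order for s in items])
        f.create_dataset("augmented", data=[s.augmented for s in items])
        f.create_dataset(
            "split_tag",
            data=np.array([s.split_tag for s in items], dtype="S8"),
        )


def load_spectrograms(path: str | Path) -> list[BeatSpectrogram]:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        sids = f["subject_id"][...]
        orders = f["order"][...]
        aug = f["augmented"][...]
        tags = [t.decode() for t in f["split_tag"][...]]
    return [
        BeatSpectrogram(int(s), v, split_tag=t, augmented=bool(a), order=int(o))
        for v, s, t, a, o in zip(values, sids, tags, aug, orders)
    ]


def save_model(arrays: list[np.ndarray], meta: dict, path: str | Path) -> None:
    """Single-file checkpoint: weight arrays plus a JSON metadata blob."""
    named = {f"arr_{i}": a for i, a in enumerate(arrays)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **named)


def load_model_arrays(path: str | Path) -> tuple[list[np.ndarray], dict]:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        n = len([k for k in f.files if k.startswith("arr_")])
        arrays = [f[f"arr_{i}"] for i in range(n)]
    return arrays, meta


def save_gallery(
    gallery: SubjectGallery, path: str | Path,
    config_hash: str = "", seed: int = 0,
) -> None:
    doc = {
        "config_hash": config_hash,
        "seed": seed,
        "epsilon": gallery.epsilon,
        "subjects": {
            int(sid): {
                "center": e.center.tolist(),
                "diag_covariance": e.diag_covariance.tolist(),
                "n_enrolled": e.n_enrolled,
                "threshold": e.threshold,
            }
            for sid, e in gallery.entries.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_gallery(path: str | Path) -> SubjectGallery:
    doc = yaml.safe_load(Path(path).read_text())
    g = SubjectGallery(epsilon=float(doc["epsilon"]))
    for sid, e in doc["subjects"].items():
        g.entries[int(sid)] = GalleryEntry(
            center=np.asarray(e["center"], dtype=np.float64),
            diag_covariance=np.asarray(e["diag_covariance"], dtype=np.float64),
            n_enrolled=int(e["n_enrolled"]),
            threshold=e["threshold"],
        )
    return g
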