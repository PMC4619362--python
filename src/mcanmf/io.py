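"""Serialization: Matrix Market matrices, CSV labels, JSON model schemas.

Histogram matrices and dictionary blocks are stored as Matrix Market files
(they are typically very sparse and high dimensional); labels and tabular
summaries as CSV; the model schema (modality names, dims, scales, rank and
fit configuration) as JSON next to the blocks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .multimodal import MCAModel, Modality, ModalitySchema, MultimodalDataset
from .nmf import FitConfig

__all__ = [
    "config_hash",
    "write_matrix",
    "read_matrix",
    "write_labels",
    "read_labels",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for provenance logs."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_matrix(path, mat: np.ndarray, sparse_threshold: float = 0.5) -> None:
    """Write a matrix as Matrix Market, sparse when mostly zero."""
    path = Path(path)
    mat = np.asarray(mat, dtype=float)
    density = np.count_nonzero(mat) / max(mat.size, 1)
    if density < sparse_threshold:
        mmwrite(str(path), sparse.csc_matrix(mat))
    else:
        mmwrite(str(path), mat)


def read_matrix(path) -> np.ndarray:
    path = Path(path)
    try:
        mat = mmread(str(path))
    except Exception as exc:  # surface the offending file
        raise ValueError(f"cannot parse Matrix Market file {path}: {exc}") from exc
    return np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)


def write_labels(path, labels) -> None:
    pd.DataFrame({"label": np.asarray(labels)}).to_csv(path, index_label="sample")


def read_labels(path) -> np.ndarray:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse label CSV {path}: {exc}") from exc
    if "label" not in df.columns:
        raise ValueError(f"label CSV {path} lacks a 'label' column")
    return df["label"].to_numpy()


def save_dataset(directory, dataset: MultimodalDataset) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mat in dataset.modalities.items():
        write_matrix(directory / f"{name}.mtx", mat)
    if dataset.labels is not None:
        write_labels(directory / "labels.csv", dataset.labels)


def load_dataset(modality_paths: dict[str, str], label_path=None) -> MultimodalDataset:
    modalities = {name: read_matrix(p) for name, p in modality_paths.items()}
    labels = read_labels(label_path) if label_path else None
    return MultimodalDataset(modalities, labels=labels)


def save_model(directory, model: MCAModel, extra_meta: dict | None = None) -> None:
    """Persist a model: one Matrix Market file per dictionary block plus a
    JSON schema carrying names, dims, scales, rank and fit configuration."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "k": model.k,
        "final_loss": model.final_loss,
        "config": dataclasses.asdict(model.config),
        "modalities": [
            {"name": m.name, "dim": m.dim, "scale": m.scale} for m in model.schema.modalities
        ],
    }
    if extra_meta:
        meta.update(extra_meta)
    meta["config_hash"] = config_hash(meta["config"])
    (directory / "schema.json").write_text(json.dumps(meta, indent=2))
    for name, block in model.blocks.items():
        write_matrix(directory / f"W_{name}.mtx", block)


def load_model(directory) -> MCAModel:
    directory = Path(directory)
    meta = json.loads((directory / "schema.json").read_text())
    schema = ModalitySchema(
        tuple(Modality(m["name"], m["dim"], m["scale"]) for m in meta["modalities"])
    )
    blocks = {m.name: read_matrix(directory / f"W_{m.name}.mtx") for m in schema.modalities}
    return MCAModel(
        schema=schema,
        blocks=blocks,
        k=meta["k"],
        config=FitConfig(**meta["config"]),
        final_loss=meta.get("final_loss"),
    )
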