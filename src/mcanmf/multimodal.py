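"""Multimodal dictionary learning by stacking modality histograms.

Each sample is perceived in several modalities (e.g. sound, motion, image),
each represented by a fixed-length nonnegative histogram.  Modalities are
normalized to comparable magnitude (mean column 1-norm of 1), vertically
stacked, and factorized with a single NMF; the fitted dictionary then splits
row-wise into per-modality blocks W_mod.  Because the blocks share the
coefficient space, an observation restricted to a subset of modalities can be
coded into the same internal representation (coefficient inference against
the stacked blocks of the observed modalities) and the expected perception in
any unobserved modality reconstructed as W_target · h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .nmf import FitConfig, fit, infer_coefficients

__all__ = [
    "Modality",
    "ModalitySchema",
    "MultimodalDataset",
    "MCAModel",
    "normalize_modalities",
    "stack",
    "split_dictionary",
    "fit_mca",
    "internal_representation",
    "reconstruct_modality",
    "append_label_modality",
]


@dataclass(frozen=True)
class Modality:
    name: str
    dim: int
    scale: float = 1.0  # multiplicative factor taking raw data to model units

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("modality dimension must be >= 1")
        if self.scale <= 0:
            raise ValueError("modality scale must be > 0")


@dataclass(frozen=True)
class ModalitySchema:
    """Ordered modality layout; the order is the canonical stacking order."""

    modalities: tuple[Modality, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.modalities]
        if len(set(names)) != len(names):
            raise ValueError("modality names must be unique")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.modalities]

    @property
    def stacked_dim(self) -> int:
        return sum(m.dim for m in self.modalities)

    def __getitem__(self, name: str) -> Modality:
        for m in self.modalities:
            if m.name == name:
                return m
        raise KeyError(f"unknown modality {name!r}")

    def row_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for m in self.modalities:
            out[m.name] = slice(start, start + m.dim)
            start += m.dim
        return out


@dataclass
class MultimodalDataset:
    """Aligned per-modality matrices; column i of every modality is scene i."""

    modalities: dict[str, np.ndarray]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = set()
        for name, mat in self.modalities.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2:
                raise ValueError(f"modality {name!r} must be a 2-D matrix")
            if (mat < 0).any():
                raise ValueError(f"modality {name!r} contains negative entries")
            self.modalities[name] = mat
            counts.add(mat.shape[1])
        if len(counts) > 1:
            raise ValueError(f"modalities disagree on sample count: {sorted(counts)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_samples:
                raise ValueError("label count does not match sample count")

    @property
    def n_samples(self) -> int:
        return next(iter(self.modalities.values())).shape[1]

    def subset(self, idx) -> "MultimodalDataset":
        return MultimodalDataset(
            {name: mat[:, idx] for name, mat in self.modalities.items()},
            labels=None if self.labels is None else self.labels[idx],
        )


@dataclass
class MCAModel:
    """A trained multimodal dictionary: per-modality blocks sharing rank k."""

    schema: ModalitySchema
    blocks: dict[str, np.ndarray]
    k: int
    config: FitConfig
    final_loss: float | None = None

    def __post_init__(self) -> None:
        for m in self.schema.modalities:
            block = np.asarray(self.blocks[m.name], dtype=float)
            if block.shape != (m.dim, self.k):
                raise ValueError(
                    f"block {m.name!r} has shape {block.shape}, expected {(m.dim, self.k)}"
                )
            self.blocks[m.name] = block

    @property
    def dictionary(self) -> np.ndarray:
        """The stacked dictionary (concatenation of blocks in schema order)."""
        return np.vstack([self.blocks[name] for name in self.schema.names])

    def scale_observation(self, observation: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Take raw-unit observations to model units using the stored
        training-set scales (held-out data is never re-normalized)."""
        return {
            name: np.asarray(mat, float) * self.schema[name].scale
            for name, mat in observation.items()
        }


def normalize_modalities(
    dataset: MultimodalDataset,
) -> tuple[MultimodalDataset, ModalitySchema]:
    """Bring every modality to mean column 1-norm 1.

    The I-divergence trades error across modalities in proportion to their
    magnitudes, so each modality matrix is divided by the mean 1-norm of its
    columns.  The applied factors are recorded in the returned schema so that
    held-out data can be scaled identically later.
    """
    scaled: dict[str, np.ndarray] = {}
    mods: list[Modality] = []
    for name, mat in dataset.modalities.items():
        mean_norm = float(np.abs(mat).sum(axis=0).mean())
        if mean_norm == 0:
            raise ValueError(f"modality {name!r} is all-zero; cannot normalize")
        scale = 1.0 / mean_norm
        scaled[name] = mat * scale
        mods.append(Modality(name=name, dim=mat.shape[0], scale=scale))
    return MultimodalDataset(scaled, labels=dataset.labels), ModalitySchema(tuple(mods))


def stack(dataset: MultimodalDataset, schema: ModalitySchema) -> np.ndarray:
    """Vertically concatenate modality matrices in schema order."""
    rows = []
    for m in schema.modalities:
        mat = dataset.modalities[m.name]
        if mat.shape[0] != m.dim:
            raise ValueError(
                f"modality {m.name!r} has {mat.shape[0]} rows, schema says {m.dim}"
            )
        rows.append(mat)
    return np.vstack(rows)


def split_dictionary(w: np.ndarray, schema: ModalitySchema) -> dict[str, np.ndarray]:
    """Partition the stacked dictionary rows back into per-modality blocks;
    exact inverse of :func:`stack` on the row partition."""
    w = np.asarray(w, dtype=float)
    if w.shape[0] != schema.stacked_dim:
        raise ValueError(
            f"dictionary has {w.shape[0]} rows, schema dims sum to {schema.stacked_dim}"
        )
    return {name: w[sl] for name, sl in schema.row_slices().items()}


def fit_mca(dataset: MultimodalDataset, config: FitConfig) -> tuple[MCAModel, np.ndarray]:
    """Normalize, stack, factorize and split: the full training pipeline.

    Returns the trained model and the training coefficient matrix H.
    """
    normalized, schema = normalize_modalities(dataset)
    v = stack(normalized, schema)
    w, h, trace = fit(v, config)
    model = MCAModel(
        schema=schema,
        blocks=split_dictionary(w, schema),
        k=config.k,
        config=config,
        final_loss=trace[-1],
    )
    return model, h


def internal_representation(
    model: MCAModel,
    observation: dict[str, np.ndarray],
    config: FitConfig | None = None,
) -> np.ndarray:
    """Code an observation over a subset of modalities into coefficients.

    ``observation`` maps modality names to d_mod×m matrices already in model
    units (apply :meth:`MCAModel.scale_observation` to raw data first).  The
    dictionary blocks of the observed modalities are stacked and the
    coefficient-only inference run against them; observing all modalities
    reduces to full-observation coding.
    """
    if not observation:
        raise ValueError("observation must cover at least one modality")
    config = config or model.config
    names = [n for n in model.schema.names if n in observation]
    unknown = set(observation) - set(model.schema.names)
    if unknown:
        raise KeyError(f"unknown modalities: {sorted(unknown)}")
    w = np.vstack([model.blocks[n] for n in names])
    v = np.vstack([np.atleast_2d(np.asarray(observation[n], float).T).T for n in names])
    return infer_coefficients(v, w, config)


def reconstruct_modality(model: MCAModel, h: np.ndarray, target: str) -> np.ndarray:
    """Expected perception in ``target`` given coefficients h: W_target · h."""
    if target not in model.schema.names:
        raise KeyError(f"unknown modality {target!r}")
    h = np.asarray(h, dtype=float)
    if h.ndim == 1:
        h = h[:, None]
    return model.blocks[target] @ h


def append_label_modality(dataset: MultimodalDataset, n_classes: int) -> MultimodalDataset:
    """Add a symbolic-label modality: a one-hot vector of length n_classes
    per sample (zeros everywhere except a one at the label's index).  Treated
    downstream exactly like any perceptual modality."""
    if dataset.labels is None:
        raise ValueError("dataset has no labels to encode")
    labels = np.asarray(dataset.labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    onehot = np.zeros((n_classes, dataset.n_samples))
    onehot[labels, np.arange(dataset.n_samples)] = 1.0
    mods = dict(dataset.modalities)
    if "label" in mods:
        raise ValueError("dataset already has a 'label' modality")
    mods["label"] = onehot
    return MultimodalDataset(mods, labels=dataset.labels)
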